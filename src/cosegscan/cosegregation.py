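"""Within-family co-segregation and cross-family gene overlap.

A variant co-segregates within a family when every sequenced affected member
carries it (under the consensus identity rules: exact for SNVs, reciprocal
>10% interval overlap for indels). Families are intersected sequentially in
the member order of the family table — a fold-left — with the first member's
representation carried as the representative. Genes are then flagged when
they carry qualifying variants in two or more families; the cross-family
match is at gene level, not allele level, since different families typically
segregate different alleles of the same gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .consensus import DEFAULT_MIN_INDEL_FRAC, index_callset, match_in_callset
from .types import AnnotatedVariant, VariantCall

logger = logging.getLogger(__name__)

__all__ = ["FamilySharedSet", "MultiFamilyGeneHit", "shared_within_family",
           "genes_in_multiple_families"]


@dataclass
class FamilySharedSet:
    """Variants carried by every member of one family."""

    family_id: str
    shared: list  # VariantCall or AnnotatedVariant, from the first member
    n_members: int

    @property
    def shared_variants(self) -> list[AnnotatedVariant]:
        return [x.variant if isinstance(x, VariantCall) else x for x in self.shared]


@dataclass
class MultiFamilyGeneHit:
    """A gene with qualifying variants in >= min_families distinct families."""

    gene: str
    families: set[str]
    variants: dict[str, list[AnnotatedVariant]]  # family_id -> variants


def shared_within_family(
    member_callsets: Sequence[Iterable],
    family_id: str = "",
    min_indel_frac: float = DEFAULT_MIN_INDEL_FRAC,
) -> FamilySharedSet:
    """Sequentially intersect the members' variant sets.

    Fold-left over the member order given: the running set starts as the
    first member's calls and keeps only those with a partner in each
    subsequent member. The first member's annotations/genotypes are the
    representatives in the output. Requires >=2 members.
    """
    callsets = [list(cs) for cs in member_callsets]
    if len(callsets) < 2:
        raise ValueError(
            f"family {family_id or '?'}: co-segregation needs >=2 members, "
            f"got {len(callsets)}"
        )
    running = callsets[0]
    for member in callsets[1:]:
        snv_index, indel_trees = index_callset(member)
        running = [
            item
            for item in running
            if match_in_callset(
                item.variant if isinstance(item, VariantCall) else item,
                snv_index, indel_trees, min_indel_frac,
            )
            is not None
        ]
    return FamilySharedSet(
        family_id=family_id, shared=running, n_members=len(callsets)
    )


def genes_in_multiple_families(
    family_sets: Mapping[str, Iterable],
    min_families: int = 2,
) -> list[MultiFamilyGeneHit]:
    """Genes whose qualifying variants recur across >= ``min_families``.

    Variants lacking a gene symbol are skipped (count logged). The overlap
    is locus-level: families contribute different alleles of the same gene.
    Output is sorted by gene symbol.
    """
    by_gene: dict[str, dict[str, list[AnnotatedVariant]]] = {}
    n_skipped = 0
    for fam, items in family_sets.items():
        for item in items:
            v = item.variant if isinstance(item, VariantCall) else item
            if v.gene is None:
                n_skipped += 1
                continue
            by_gene.setdefault(v.gene, {}).setdefault(fam, []).append(v)
    if n_skipped:
        logger.info("genes_in_multiple_families: skipped %d variants without "
                    "gene symbol", n_skipped)
    hits = [
        MultiFamilyGeneHit(gene=g, families=set(fams), variants=fams)
        for g, fams in by_gene.items()
        if len(fams) >= min_families
    ]
    hits.sort(key=lambda h: h.gene)
    return hits
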