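"""Dual-caller consensus: the agreement set between two callers per sample.

Two variant callers disagree substantially on raw output; the pipeline keeps
only variants detected by both. SNVs match on exact (chrom, pos, ref, alt)
identity. Indels (and complex variants) match on fractional interval overlap:
two indels are the same event when their genomic intervals reciprocally
overlap by strictly more than ``min_frac`` (default 10%) of each interval's
length. Reciprocity makes indel identity symmetric; the strict inequality
means a fraction of exactly 0.10 does not match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .types import AnnotatedVariant, SampleCallset, VariantCall, variant_key

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusCallset",
    "hard_filter",
    "snv_identical",
    "indel_interval",
    "indel_identical",
    "intersect_callsets",
]

DEFAULT_MIN_INDEL_FRAC = 0.10


@dataclass
class ConsensusCallset:
    """Variants retained by both callers for one sample.

    ``provenance`` maps each retained variant's key to the matching variant
    found in the other caller's callset. Annotations and genotypes come from
    the first caller's representation.
    """

    sample_id: str
    calls: list[VariantCall]
    provenance: dict[tuple, AnnotatedVariant] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    @property
    def variants(self) -> list[AnnotatedVariant]:
        return [c.variant for c in self.calls]


def hard_filter(
    callset: SampleCallset, qual_min: float = 30.0, depth_min: int = 10
) -> SampleCallset:
    """Retain calls with quality >= qual_min and depth >= depth_min.

    Calls with absent quality or depth fail the filter (and are logged):
    a call that cannot demonstrate its quality is not high-confidence.
    Thresholds of (0, 0) make the filter the identity.
    """
    kept: list[VariantCall] = []
    n_absent = 0
    for call in callset.calls:
        q, dp = call.variant.qual, call.depth
        if (qual_min > 0 and q is None) or (depth_min > 0 and dp is None):
            n_absent += 1
            continue
        if (q is None or q >= qual_min) and (dp is None or dp >= depth_min):
            kept.append(call)
    if n_absent:
        logger.info(
            "hard_filter(%s/%s): %d calls dropped for absent qual/depth",
            callset.sample_id, callset.caller_tag, n_absent,
        )
    return SampleCallset(callset.sample_id, callset.caller_tag, kept)


def snv_identical(a: AnnotatedVariant, b: AnnotatedVariant) -> bool:
    """Exact identity for SNVs: same (chrom, pos, ref, alt)."""
    if a.vclass != "snv" or b.vclass != "snv":
        raise ValueError("snv_identical requires two SNVs")
    return a.key == b.key


def indel_interval(v: AnnotatedVariant) -> tuple[int, int]:
    """0-based half-open genomic interval occupied by an indel.

    Deletions and complex variants span the reference allele,
    ``[pos-1, pos-1+len(ref))``; insertions occupy a 1-bp anchor
    ``[pos-1, pos)`` at the insertion point.
    """
    if v.vclass == "snv":
        raise ValueError("indel_interval is undefined for SNVs")
    start = v.pos - 1
    if v.vclass == "insertion":
        return (start, start + 1)
    return (start, start + len(v.ref))


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def indel_identical(
    a: AnnotatedVariant, b: AnnotatedVariant, min_frac: float = DEFAULT_MIN_INDEL_FRAC
) -> bool:
    """Reciprocal fractional-overlap identity for indels.

    True iff the shared span exceeds ``min_frac`` of *both* intervals'
    lengths (strictly: a fraction of exactly ``min_frac`` fails). Variants on
    different chromosomes never match.
    """
    if not (0.0 < min_frac <= 1.0):
        raise ValueError(f"min_frac {min_frac} outside (0, 1]")
    if a.chrom != b.chrom:
        return False
    ia, ib = indel_interval(a), indel_interval(b)
    ov = _overlap_len(ia, ib)
    if ov == 0:
        return False
    return ov / (ia[1] - ia[0]) > min_frac and ov / (ib[1] - ib[0]) > min_frac


def match_in_callset(
    v: AnnotatedVariant,
    snv_index: dict[tuple, AnnotatedVariant],
    indel_trees: dict[str, IntervalTree],
    min_frac: float = DEFAULT_MIN_INDEL_FRAC,
) -> Optional[AnnotatedVariant]:
    """Best partner for ``v`` in an indexed callset, or None.

    SNVs use exact-key lookup. Indels take the greedy maximum-overlap
    candidate among those passing the reciprocal ``min_frac`` rule, with ties
    broken leftmost (then by allele strings) for determinism.
    """
    if v.vclass == "snv":
        return snv_index.get(v.key)
    tree = indel_trees.get(v.chrom)
    if tree is None:
        return None
    ia = indel_interval(v)
    best: Optional[tuple] = None
    for iv in tree.overlap(ia[0], ia[1]):
        cand: AnnotatedVariant = iv.data
        if indel_identical(v, cand, min_frac):
            ov = _overlap_len(ia, indel_interval(cand))
            rank = (-ov, indel_interval(cand)[0], cand.pos, cand.ref, cand.alt)
            if best is None or rank < best[0]:
                best = (rank, cand)
    return None if best is None else best[1]


def index_callset(
    calls,
) -> tuple[dict[tuple, AnnotatedVariant], dict[str, IntervalTree]]:
    """Build the SNV key index and per-chromosome indel interval trees."""
    snv_index: dict[tuple, AnnotatedVariant] = {}
    indel_trees: dict[str, IntervalTree] = {}
    for c in calls:
        v = c.variant if isinstance(c, VariantCall) else c
        if v.vclass == "snv":
            snv_index[v.key] = v
        else:
            s, e = indel_interval(v)
            indel_trees.setdefault(v.chrom, IntervalTree()).addi(s, e, v)
    return snv_index, indel_trees


def intersect_callsets(
    a: SampleCallset,
    b: SampleCallset,
    min_indel_frac: float = DEFAULT_MIN_INDEL_FRAC,
) -> ConsensusCallset:
    """Consensus of two callers' callsets for the same sample.

    Every SNV of ``a`` with an identical partner in ``b`` is retained, as is
    every indel of ``a`` with a reciprocal->min_frac overlap partner in
    ``b``. Annotations and genotype are taken from ``a``; the partner is
    recorded as provenance. No genotype concordance is required.
    """
    if a.sample_id != b.sample_id:
        raise ValueError(
            f"cannot intersect callsets of different samples "
            f"({a.sample_id!r} vs {b.sample_id!r})"
        )
    snv_index, indel_trees = index_callset(b.calls)
    kept: list[VariantCall] = []
    provenance: dict[tuple, AnnotatedVariant] = {}
    for call in a.calls:
        partner = match_in_callset(call.variant, snv_index, indel_trees, min_indel_frac)
        if partner is not None:
            kept.append(call)
            provenance[variant_key(call)] = partner
    return ConsensusCallset(sample_id=a.sample_id, calls=kept, provenance=provenance)
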