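"""The rare/conserved/impactful/deleterious filter cascade.

Applied to consensus variants, in order:

1. **rarity** — keep variants below 1% population allele frequency in *both*
   gnomAD-popmax and TOPMed (a variant at >=1% in either database is removed);
2. **conservation** — keep variants at conserved positions, PhastCons-7-way
   strictly above 0.1 (indels typically lack a score and pass by default);
3. **impact** — keep high/moderate-impact consequences (stop-gained,
   frameshift, splice-disrupting, missense, inframe indels, ...); synonymous
   and non-coding classes are removed;
4. **missense deleteriousness** — a missense variant called benign by
   PolyPhen *and* tolerated by SIFT is removed; one damaging verdict from
   either tool retains it.

Each stage is a pure predicate, so the cascade is order-independent over its
input set and idempotent. ``apply_cascade`` records a per-stage count ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .types import (
    AnnotatedVariant,
    IndeterminateComparisonError,
    VariantCall,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CascadeConfig",
    "FilterCascadeResult",
    "LedgerRow",
    "is_rare",
    "is_conserved",
    "is_impactful",
    "missense_excluded",
    "apply_cascade",
    "CONSEQUENCE_TIERS",
]

#: Consequence-term -> impact-tier map used when a variant carries only a
#: consequence annotation. Approximates the Ensembl/Slivar "impactful"
#: classification; override via CascadeConfig.consequence_tiers.
CONSEQUENCE_TIERS: dict[str, str] = {
    # high impact
    "stop_gained": "high",
    "stop gained": "high",
    "frameshift": "high",
    "frameshift_variant": "high",
    "splice_acceptor": "high",
    "splice_acceptor_variant": "high",
    "splice_donor": "high",
    "splice_donor_variant": "high",
    "start_lost": "high",
    "stop_lost": "high",
    "transcript_ablation": "high",
    # moderate impact
    "missense": "moderate",
    "missense_variant": "moderate",
    "inframe_insertion": "moderate",
    "inframe_deletion": "moderate",
    "protein_altering": "moderate",
    "protein_altering_variant": "moderate",
    # low / modifier
    "synonymous": "low",
    "synonymous_variant": "low",
    "splice_region": "low",
    "splice_region_variant": "low",
    "stop_retained": "low",
    "start_retained": "low",
    "intronic": "modifier",
    "intron_variant": "modifier",
    "5_prime_utr": "modifier",
    "3_prime_utr": "modifier",
    "utr": "modifier",
    "upstream": "modifier",
    "upstream_gene_variant": "modifier",
    "downstream": "modifier",
    "downstream_gene_variant": "modifier",
    "intergenic": "modifier",
    "intergenic_variant": "modifier",
    "non_coding": "modifier",
}

_MISSENSE_TERMS = frozenset({"missense", "missense_variant"})


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and policies for the filter cascade."""

    af_max: float = 0.01
    phastcons_min: float = 0.1
    absent_conservation_passes: bool = True
    consequence_tiers: Optional[dict[str, str]] = None

    def tier_for(self, consequence: str) -> str:
        table = self.consequence_tiers or CONSEQUENCE_TIERS
        key = consequence.strip().lower().replace(" ", "_")
        if key not in table and consequence.strip().lower() not in table:
            raise ValueError(f"unknown consequence term {consequence!r}")
        return table.get(key, table.get(consequence.strip().lower()))


def _freq_below(
    freq, threshold: float, v: AnnotatedVariant, label: str
) -> bool:
    if freq is None:
        logger.debug("variant %s lacks %s annotation; treated as passing", v.key, label)
        return True
    try:
        return freq.is_below(threshold)
    except IndeterminateComparisonError as exc:
        raise IndeterminateComparisonError(
            f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt}: {exc}"
        ) from exc


def is_rare(v: AnnotatedVariant, af_max: float = 0.01) -> bool:
    """True iff the variant is below ``af_max`` in both gnomAD-popmax and
    TOPMed (removed when at or above the threshold in either database).

    Absent annotations pass (logged). A censored annotation whose bound
    straddles the threshold raises, naming the variant.
    """
    return _freq_below(v.gnomad_popmax_af, af_max, v, "gnomAD popmax") and _freq_below(
        v.topmed_af, af_max, v, "TOPMed"
    )


def is_conserved(
    v: AnnotatedVariant, pc_min: float = 0.1, absent_passes: bool = True
) -> bool:
    """True iff PhastCons-7-way strictly exceeds ``pc_min``.

    Variants without a conservation score (mostly indels — annotation
    coverage is patchy there) pass by default.
    """
    if v.phastcons7 is None:
        return absent_passes
    return v.phastcons7 > pc_min


def is_impactful(v: AnnotatedVariant, config: CascadeConfig = CascadeConfig()) -> bool:
    """True iff the variant's predicted impact tier is high or moderate.

    Uses ``impact_tier`` when annotated; otherwise maps the consequence term
    through the packaged tier table. An unknown consequence term raises.
    """
    if v.impact_tier is not None:
        return v.impact_tier in ("high", "moderate")
    if v.consequence is None:
        raise ValueError(
            f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt} has neither "
            "impact_tier nor consequence annotation"
        )
    return config.tier_for(v.consequence) in ("high", "moderate")


def _is_missense(v: AnnotatedVariant) -> bool:
    return v.consequence is not None and (
        v.consequence.strip().lower().replace(" ", "_") in _MISSENSE_TERMS
    )


def missense_excluded(v: AnnotatedVariant) -> bool:
    """True iff a missense variant is called benign/tolerated by *both* tools.

    A variant with one damaging verdict (SIFT deleterious or PolyPhen
    probably/possibly damaging) is retained; only the unanimous
    tolerated-and-benign combination is excluded. Absent labels are treated
    as non-exculpatory (not benign/tolerated).
    """
    if not _is_missense(v):
        raise ValueError("missense_excluded applies only to missense variants")
    return v.sift_label == "tolerated" and v.polyphen_label == "benign"


@dataclass(frozen=True)
class LedgerRow:
    stage: str
    input_count: int
    removed_count: int
    output_count: int


@dataclass
class FilterCascadeResult:
    """Surviving items plus the per-stage count ledger.

    Ledger counts telescope: each stage's output is the next stage's input
    and removed + output == input at every stage.
    """

    surviving: list
    ledger: list[LedgerRow] = field(default_factory=list)

    @property
    def surviving_variants(self) -> list[AnnotatedVariant]:
        return [_as_variant(x) for x in self.surviving]

    def ledger_dict(self) -> list[dict]:
        return [vars(r) for r in self.ledger]


def _as_variant(item) -> AnnotatedVariant:
    return item.variant if isinstance(item, VariantCall) else item


def apply_cascade(
    items: Iterable, config: CascadeConfig = CascadeConfig()
) -> FilterCascadeResult:
    """Run the four-stage cascade over variants (or variant calls).

    Accepts bare :class:`AnnotatedVariant` objects or genotype-carrying
    :class:`VariantCall` objects; the filter decisions depend only on the
    variant annotations. Returns survivors in input order plus the ledger.
    """
    stages = [
        ("rare_af", lambda v: is_rare(v, config.af_max)),
        ("conserved", lambda v: is_conserved(
            v, config.phastcons_min, config.absent_conservation_passes)),
        ("impactful", lambda v: is_impactful(v, config)),
        ("missense_not_benign_tolerated",
         lambda v: not missense_excluded(v) if _is_missense(v) else True),
    ]
    current = list(items)
    ledger: list[LedgerRow] = []
    for name, pred in stages:
        n_in = len(current)
        current = [x for x in current if pred(_as_variant(x))]
        ledger.append(LedgerRow(name, n_in, n_in - len(current), len(current)))
    return FilterCascadeResult(surviving=current, ledger=ledger)
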