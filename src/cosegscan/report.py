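"""Descriptive cohort and variant summaries, censoring-aware.

Population allele frequencies are often reported only as bounds ("<0.001").
Summary statistics here never impute those: the censoring-aware median places
a censored value ``<v`` below ``v`` itself and below every uncensored value
``>= v``, and *raises* whenever the censoring pattern makes the identity of
the median genuinely ambiguous, rather than guessing. Quartile summaries
that land on censored values are reported as explicit bounds.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .types import AnnotatedVariant, CensoredFrequency, FamilyCohort

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSummary",
    "VariantSummary",
    "AmbiguousCensoringError",
    "summarize_cohort",
    "censored_median",
    "summarize_variants",
    "crossref_gene_lists",
]


class AmbiguousCensoringError(ValueError):
    """The censoring pattern leaves the requested order statistic undefined."""


@dataclass(frozen=True)
class CohortSummary:
    """Participant-level demographics of a family cohort."""

    n_participants: int
    n_families: int
    n_female: int
    pct_female: int
    n_bilateral: int
    pct_bilateral: int
    median_age: float
    age_range: tuple[float, float]


def summarize_cohort(cohort: FamilyCohort) -> CohortSummary:
    """Demographic summary: counts, rounded percentages, median age, range.

    The median of an even number of ages is the mean of the middle two;
    participants without a recorded age are excluded from the median and
    range (logged). Percentages are rounded to the nearest integer.
    """
    samples = cohort.sample_ids
    if not samples:
        raise ValueError("empty cohort")
    phen = [cohort.phenotypes[s] for s in samples if s in cohort.phenotypes]
    ages = [p.age_at_diagnosis for p in phen if p.age_at_diagnosis is not None]
    n_missing_age = len(phen) - len(ages)
    if n_missing_age:
        logger.info("summarize_cohort: %d participants without recorded age",
                    n_missing_age)
    if not ages:
        raise ValueError("no participant has a recorded age")
    n = len(samples)
    n_female = sum(1 for p in phen if p.sex == "female")
    n_bilateral = sum(1 for p in phen if p.bilateral)
    return CohortSummary(
        n_participants=n,
        n_families=cohort.n_families,
        n_female=n_female,
        pct_female=round(100 * n_female / n),
        n_bilateral=n_bilateral,
        pct_bilateral=round(100 * n_bilateral / n),
        median_age=float(statistics.median(ages)),
        age_range=(min(ages), max(ages)),
    )


def _definitely_less(e: CensoredFrequency, f: CensoredFrequency) -> bool:
    """True iff e's true value is certainly < f's under censoring semantics."""
    if not e.censored and not f.censored:
        return e.value < f.value
    if e.censored and not f.censored:
        # true(e) in [0, e.value): certainly below an uncensored f >= bound
        return e.value <= f.value
    # uncensored-vs-censored and censored-vs-censored are never definite
    return False


def _definitely_greater(e: CensoredFrequency, f: CensoredFrequency) -> bool:
    return _definitely_less(f, e)


def _rank_candidates(
    values: Sequence[CensoredFrequency], k: int
) -> list[CensoredFrequency]:
    """Elements that can occupy rank ``k`` under some consistent ordering."""
    n = len(values)
    out = []
    for i, e in enumerate(values):
        below = sum(1 for j, f in enumerate(values) if j != i and _definitely_less(f, e))
        above = sum(1 for j, f in enumerate(values) if j != i and _definitely_greater(f, e))
        if below <= k and above <= n - 1 - k:
            out.append(e)
    return out


def _report_of(e: CensoredFrequency) -> tuple[float, bool]:
    return (e.value, e.censored)


def censored_median(values: Sequence[CensoredFrequency]) -> CensoredFrequency:
    """Median of possibly-censored frequencies.

    A censored value ``<v`` sorts below ``v`` itself and below every
    uncensored value ``>= v``; its order relative to smaller uncensored
    values is unknown. The median is returned uncensored if an uncensored
    value occupies the median position in every ordering consistent with the
    censoring, censored (with its bound) if only censored values with one
    common bound can occupy it, and :class:`AmbiguousCensoringError` is
    raised otherwise.

    For an even count the two middle positions are combined: the mean of two
    unambiguous uncensored values, or the common censored bound.
    """
    vals = list(values)
    if not vals:
        raise ValueError("censored_median of empty list")
    n = len(vals)

    def resolve(k: int) -> CensoredFrequency:
        cands = {_report_of(e) for e in _rank_candidates(vals, k)}
        if len(cands) != 1:
            raise AmbiguousCensoringError(
                f"median position {k} is ambiguous under censoring: "
                f"candidates {sorted(cands)}"
            )
        value, cens = next(iter(cands))
        return CensoredFrequency(value, censored=cens)

    if n % 2 == 1:
        return resolve(n // 2)
    lo, hi = resolve(n // 2 - 1), resolve(n // 2)
    if not lo.censored and not hi.censored:
        return CensoredFrequency((lo.value + hi.value) / 2)
    if lo.censored and hi.censored and lo.value == hi.value:
        return lo
    raise AmbiguousCensoringError(
        "even-count median mixes censored and uncensored middle values"
    )


@dataclass(frozen=True)
class VariantSummary:
    """Summary of a qualifying-variant list (allele frequencies, conservation)."""

    n_variants: int
    n_genes: int
    median_gnomad_af: CensoredFrequency
    iqr_gnomad_af: float
    iqr_is_upper_bound: bool
    median_topmed_af: CensoredFrequency
    n_conserved_high: int
    conservation_threshold: float
    max_af_percent: float
    max_af_is_upper_bound: bool
    quartile_rule: str = "linear interpolation"


def _quartiles_with_censoring(
    freqs: Sequence[CensoredFrequency],
) -> tuple[float, bool]:
    """(IQR, is_upper_bound) with censored values at their upper bounds.

    Quartiles use numpy's linear interpolation over values sorted with
    censored entries placed at (just below) their bounds. If any value
    contributing to a quartile is censored, the IQR is only an upper bound
    (the true censored values could be arbitrarily small) and is flagged.
    """
    order = sorted(freqs, key=lambda f: (f.value, not f.censored))
    xs = np.array([f.value for f in order])
    cens = np.array([f.censored for f in order])
    n = len(xs)
    q1, q3 = np.percentile(xs, [25, 75])
    # indices touched by the interpolation at each quartile
    touched = set()
    for q in (0.25, 0.75):
        h = (n - 1) * q
        touched.update({int(np.floor(h)), int(np.ceil(h))})
    bound = bool(cens[sorted(touched)].any())
    if bound:
        logger.info("IQR involves censored values; reported as an upper bound")
    return float(q3 - q1), bound


def summarize_variants(
    variants: Sequence[AnnotatedVariant], conservation_threshold: float = 0.9
) -> VariantSummary:
    """Frequency and conservation summary of a variant list.

    ``n_conserved_high`` counts PhastCons scores strictly above the
    threshold. ``max_af_percent`` is 100x the largest *uncensored* gnomAD
    popmax frequency; if every frequency is censored it is the largest bound,
    flagged as an upper bound.
    """
    if not variants:
        raise ValueError("summarize_variants of empty list")
    gnomad = [v.gnomad_popmax_af for v in variants if v.gnomad_popmax_af is not None]
    topmed = [v.topmed_af for v in variants if v.topmed_af is not None]
    if not gnomad or not topmed:
        raise ValueError("variants lack frequency annotations")
    uncensored = [f.value for f in gnomad if not f.censored]
    if uncensored:
        max_af, max_bound = max(uncensored), False
    else:
        max_af, max_bound = max(f.value for f in gnomad), True
    iqr, iqr_bound = _quartiles_with_censoring(gnomad)
    return VariantSummary(
        n_variants=len(variants),
        n_genes=len({v.gene for v in variants if v.gene is not None}),
        median_gnomad_af=censored_median(gnomad),
        iqr_gnomad_af=iqr,
        iqr_is_upper_bound=iqr_bound,
        median_topmed_af=censored_median(topmed),
        n_conserved_high=sum(
            1 for v in variants
            if v.phastcons7 is not None and v.phastcons7 > conservation_threshold
        ),
        conservation_threshold=conservation_threshold,
        max_af_percent=100.0 * max_af,
        max_af_is_upper_bound=max_bound,
    )


def crossref_gene_lists(
    candidates: Iterable[str],
    external_lists: Mapping[str, Iterable[str]],
) -> tuple[dict[str, set[str]], set[str]]:
    """Intersect candidate genes with named external lists.

    Returns (per-list intersections, intersection across all lists —
    candidates found in every external list).
    """
    cand = set(candidates)
    per_list = {name: cand & set(genes) for name, genes in external_lists.items()}
    common = cand.copy()
    for inter in per_list.values():
        common &= inter
    if not external_lists:
        common = set()
    return per_list, common
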