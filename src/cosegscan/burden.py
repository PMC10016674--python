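"""Gene-based mutation-burden testing against public control allele counts.

Qualifying variants (cascade survivors) are collapsed per gene and carriers
are counted in the case cohort under two models:

* **dominant** — a sample carries >=1 qualifying allele in the gene;
* **recessive** — a sample carries >=2 qualifying alleles (hom-alt, or two
  het sites in the same gene counted as a putative compound het; phase is
  not observed, so any two alleles qualify).

Because public controls (gnomAD-style) provide only aggregate allele counts,
control carrier counts are *expected* counts derived from the per-site allele
frequencies under site independence: dominant carriers as
``N * (1 - prod_i(1 - af_i))``, recessive carriers as
``N * (sum_i af_i)^2`` (Hardy–Weinberg approximation), rounded to integers
for the exact test. Control sites must pass a sequencing-depth QC (fraction
of control samples above the depth cutoff) before contributing.

Each gene's case-vs-control carrier table is tested with a two-sided Fisher
exact test: the p-value is the sum of hypergeometric probabilities, at the
observed margins, of every table no more probable than the observed one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .types import AnnotatedVariant, VariantCall, variant_key
from .vcfio import ControlSiteRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GeneBurdenRow",
    "site_qc",
    "case_carrier_counts",
    "control_carrier_counts",
    "fisher_two_sided",
    "burden_table",
]

#: Relative slack when comparing table probabilities to the observed one;
#: absorbs floating-point noise in "equally probable" opposite-tail tables.
_PROB_SLACK = 1e-7


def site_qc(record: ControlSiteRecord, min_depth_fraction: float = 0.90) -> bool:
    """Control-site QC: enough control samples well covered at the position.

    Passes iff ``depth_pass_fraction >= min_depth_fraction`` (inclusive).
    """
    return record.depth_pass_fraction >= min_depth_fraction


def case_carrier_counts(
    gene: str,
    cohort_calls: Mapping[str, Iterable[VariantCall]],
) -> tuple[int, int]:
    """(dominant, recessive) carrier counts for one gene in the case cohort.

    ``cohort_calls`` maps sample id -> that sample's qualifying variant
    calls. A het site contributes one allele, a hom-alt site two; samples
    with >=1 allele in the gene count as dominant carriers, >=2 alleles
    (hom-alt or multi-site) as recessive carriers.
    """
    dom = rec = 0
    for sample_id, calls in cohort_calls.items():
        alleles = sum(c.allele_count for c in calls if c.variant.gene == gene)
        if alleles >= 1:
            dom += 1
        if alleles >= 2:
            rec += 1
    return dom, rec


def control_carrier_counts(
    gene: str,
    control_records: Sequence[ControlSiteRecord],
    n_controls: int,
) -> tuple[int, int]:
    """Expected (dominant, recessive) control carrier counts for one gene.

    ``control_records`` are the QC-passed control sites matching the gene's
    qualifying variants. Sites with zero allele number are skipped and logged.
    Dominant: ``round(N * (1 - prod(1 - af_i)))`` — probability a control
    individual carries at least one qualifying allele under independence.
    Recessive: ``round(N * (sum af_i)^2)`` capped at N — Hardy–Weinberg
    probability of two qualifying alleles with the per-gene frequency pooled
    across sites.
    """
    prod_non = 1.0
    af_sum = 0.0
    for r in control_records:
        if r.control_an == 0:
            logger.warning("control site %s has AN=0; skipped", r.key)
            continue
        prod_non *= 1.0 - r.af
        af_sum += r.af
    # half-up rounding: an expected half-carrier counts as one
    dom = math.floor(n_controls * (1.0 - prod_non) + 0.5)
    rec = min(n_controls, math.floor(n_controls * af_sum**2 + 0.5))
    return dom, rec


def _lchoose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Rows are cases / controls, columns carrier / non-carrier. With the
    margins fixed, sums the hypergeometric probabilities of every table
    whose probability does not exceed the observed table's (with a small
    relative slack for floating-point ties). Degenerate margins give 1.0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("fisher_two_sided requires nonnegative counts")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 == 0 or row1 == n or col1 == 0 or col1 == n:
        return 1.0
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    logc = _lchoose(n, col1)
    logpmf = [
        _lchoose(row1, x) + _lchoose(n - row1, col1 - x) - logc
        for x in range(lo, hi + 1)
    ]
    thresh = logpmf[a - lo] + math.log1p(_PROB_SLACK)
    p = sum(math.exp(lp) for lp in logpmf if lp <= thresh)
    return min(1.0, p)


@dataclass
class GeneBurdenRow:
    """Per-gene burden result: carrier counts and Fisher p-values."""

    gene: str
    n_case_carriers_dom: int
    n_case_carriers_rec: int
    n_cases: int
    n_control_carriers_dom: int
    n_control_carriers_rec: int
    n_controls: int
    p_dom: float
    p_rec: float
    variant_count: int
    p_dom_bonferroni: float = 1.0
    p_rec_bonferroni: float = 1.0


def burden_table(
    cohort_calls: Mapping[str, Iterable[VariantCall]],
    controls: Sequence[ControlSiteRecord],
    n_controls: int,
    min_depth_fraction: float = 0.90,
) -> list[GeneBurdenRow]:
    """Per-gene burden test of the case cohort against public controls.

    One row per gene with at least one qualifying case variant. Control
    sites are matched to genes through the case cohort's variant keys, after
    depth QC. Rows come back sorted by dominant p-value, ties broken by gene
    symbol; a Bonferroni column (over the number of genes tested) is
    included alongside the raw p-values.
    """
    cohort_calls = {s: list(calls) for s, calls in cohort_calls.items()}
    n_cases = len(cohort_calls)

    gene_of_key: dict[tuple, str] = {}
    genes: dict[str, set[tuple]] = {}
    for calls in cohort_calls.values():
        for call in calls:
            g = call.variant.gene
            if g is None:
                continue
            gene_of_key[variant_key(call)] = g
            genes.setdefault(g, set()).add(variant_key(call))

    qc_controls: dict[str, list[ControlSiteRecord]] = {}
    for r in controls:
        if not site_qc(r, min_depth_fraction):
            continue
        g = gene_of_key.get(r.key)
        if g is not None:
            qc_controls.setdefault(g, []).append(r)

    rows: list[GeneBurdenRow] = []
    for gene, keys in genes.items():
        dom_case, rec_case = case_carrier_counts(gene, cohort_calls)
        dom_ctl, rec_ctl = control_carrier_counts(
            gene, qc_controls.get(gene, []), n_controls
        )
        p_dom = fisher_two_sided(
            dom_case, n_cases - dom_case, dom_ctl, n_controls - dom_ctl
        )
        p_rec = fisher_two_sided(
            rec_case, n_cases - rec_case, rec_ctl, n_controls - rec_ctl
        )
        rows.append(GeneBurdenRow(
            gene=gene,
            n_case_carriers_dom=dom_case,
            n_case_carriers_rec=rec_case,
            n_cases=n_cases,
            n_control_carriers_dom=dom_ctl,
            n_control_carriers_rec=rec_ctl,
            n_controls=n_controls,
            p_dom=p_dom,
            p_rec=p_rec,
            variant_count=len(keys),
        ))
    m = len(rows)
    for r in rows:
        r.p_dom_bonferroni = min(1.0, r.p_dom * m)
        r.p_rec_bonferroni = min(1.0, r.p_rec * m)
    rows.sort(key=lambda r: (r.p_dom, r.gene))
    return rows
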