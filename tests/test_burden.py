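"""Gene-burden collapsing, carrier counting and the Fisher exact test."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact

from cosegscan import (
    ControlSiteRecord,
    burden_table,
    case_carrier_counts,
    control_carrier_counts,
    fisher_two_sided,
    site_qc,
)
from cosegscan.simulate import generate_null_burden
from tests.conftest import make_call, make_passing_variant


def _ctl(pos=100, ac=1, an=1000, dpf=0.95, chrom="chr1", ref="A", alt="G"):
    return ControlSiteRecord(chrom, pos, ref, alt, ac, an, dpf)


class TestSiteQC:
    @pytest.mark.parametrize("dpf,expected", [(0.95, True), (0.90, True), (0.5, False)])
    def test_inclusive_threshold(self, dpf, expected):
        assert site_qc(_ctl(dpf=dpf)) is expected


class TestCaseCarrierCounts:
    def test_single_het_is_dominant_only(self):
        calls = {"S1": [make_call(make_passing_variant(gene="G1"))]}
        assert case_carrier_counts("G1", calls) == (1, 0)

    def test_hom_alt_counts_in_both_models(self):
        calls = {"S1": [make_call(make_passing_variant(gene="G1"), genotype="hom_alt")]}
        assert case_carrier_counts("G1", calls) == (1, 1)

    def test_two_het_sites_make_putative_compound_het(self):
        calls = {"S1": [
            make_call(make_passing_variant(gene="G1", pos=100)),
            make_call(make_passing_variant(gene="G1", pos=200)),
        ]}
        assert case_carrier_counts("G1", calls) == (1, 1)

    def test_hand_enumerated_toy_cohort(self):
        """3 samples: compound het, single het, non-carrier in gene G1."""
        g1a = make_passing_variant(gene="G1", pos=100)
        g1b = make_passing_variant(gene="G1", pos=200)
        g2 = make_passing_variant(gene="G2", pos=300)
        calls = {
            "S1": [make_call(g1a), make_call(g1b)],
            "S2": [make_call(g1a)],
            "S3": [make_call(g2, genotype="hom_alt")],
        }
        assert case_carrier_counts("G1", calls) == (2, 1)
        assert case_carrier_counts("G2", calls) == (1, 1)
        assert case_carrier_counts("G3", calls) == (0, 0)

    def test_order_invariance(self):
        a = make_passing_variant(gene="G1", pos=1)
        b = make_passing_variant(gene="G1", pos=2)
        fwd = case_carrier_counts("G1", {"S1": [make_call(a), make_call(b)]})
        rev = case_carrier_counts("G1", {"S1": [make_call(b), make_call(a)]})
        assert fwd == rev


class TestControlCarrierCounts:
    def test_single_site_half_carrier_rounds_up(self):
        dom, rec = control_carrier_counts("G", [_ctl(ac=1, an=1000)], 500)
        assert dom == 1  # 500 * (1 - 0.999) = 0.5, half-up
        assert rec == 0

    def test_no_sites_give_zero(self):
        assert control_carrier_counts("G", [], 500) == (0, 0)

    def test_two_half_frequency_sites(self):
        recs = [_ctl(pos=1, ac=500, an=1000), _ctl(pos=2, ac=500, an=1000)]
        dom, rec = control_carrier_counts("G", recs, 4)
        assert dom == 3  # 4 * (1 - 0.25)
        assert rec == 4  # 4 * (0.5 + 0.5)^2 capped at n_controls

    def test_zero_an_site_skipped(self):
        recs = [ControlSiteRecord("chr1", 1, "A", "G", 0, 0, 0.95)]
        assert control_carrier_counts("G", recs, 100) == (0, 0)

    def test_against_monte_carlo_genotype_sampling(self):
        """Expected dominant carriers match simulation at the site AFs."""
        rng = np.random.default_rng(0)
        afs = [0.01, 0.03, 0.002]
        recs = [_ctl(pos=i, ac=int(af * 10000), an=10000) for i, af in enumerate(afs, 1)]
        n = 2000
        dom, _ = control_carrier_counts("G", recs, n)
        sims = []
        for _ in range(300):
            carrier = np.zeros(n, dtype=bool)
            for af in afs:
                carrier |= rng.random(n) < af
            sims.append(carrier.sum())
        assert abs(dom - np.mean(sims)) < 3 * np.std(sims) / math.sqrt(300) + 1


def brute_force_fisher(a, b, c, d):
    """Exact-rational enumeration over all tables with the observed margins."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        return Fraction(1)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    numer = {x: math.comb(row1, x) * math.comb(n - row1, col1 - x)
             for x in range(lo, hi + 1)}
    obs = numer[a]
    total = sum(v for v in numer.values() if v <= obs)
    return Fraction(total, math.comb(n, col1))


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((1, 1, 1, 1), 1.0),
            ((2, 0, 0, 2), 1 / 3),
            ((0, 5, 0, 5), 1.0),
            ((5, 0, 0, 0), 1.0),
            ((0, 0, 0, 0), 1.0),
        ],
    )
    def test_frozen_examples(self, table, expected):
        assert fisher_two_sided(*table) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 2, 3, 4)

    def test_against_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            _, p_scipy = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert fisher_two_sided(a, b, c, d) == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)

    def test_against_exact_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            oracle = float(brute_force_fisher(a, b, c, d))
            assert fisher_two_sided(a, b, c, d) == pytest.approx(oracle, abs=1e-9)

    def test_enrichment_direction_monotone(self):
        """With margins fixed, moving case carriers above expectation never
        increases the two-sided p."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            row1 = int(rng.integers(2, 25))
            row2 = int(rng.integers(2, 25))
            col1 = int(rng.integers(1, row1 + row2))
            lo = max(0, col1 - row2)
            hi = min(row1, col1)
            expected = row1 * col1 / (row1 + row2)
            start = max(lo, math.ceil(expected))
            ps = [
                fisher_two_sided(a, row1 - a, col1 - a, row2 - (col1 - a))
                for a in range(start, hi + 1)
            ]
            assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestBurdenTable:
    def test_planted_excess_ranks_first(self):
        """All 21 cases carrying a gene at control AF 1e-4 gives p << 1e-10."""
        v = make_passing_variant(gene="HIT", pos=100)
        w = make_passing_variant(gene="NULLG", pos=500)
        calls = {f"S{i}": [make_call(v)] for i in range(21)}
        calls["S0"].append(make_call(w))
        controls = [
            _ctl(pos=100, ac=2, an=20000, dpf=0.99),
            _ctl(pos=500, ac=10, an=20000, dpf=0.99),
        ]
        rows = burden_table(calls, controls, n_controls=10000)
        assert rows[0].gene == "HIT"
        assert rows[0].p_dom < 1e-10
        assert rows[0].n_case_carriers_dom == 21

    def test_matched_frequency_gene_is_null(self):
        """Case carrier frequency equal to control carrier frequency -> p ~ 1."""
        v = make_passing_variant(gene="G", pos=100)
        calls = {f"S{i}": ([make_call(v)] if i < 2 else []) for i in range(20)}
        controls = [_ctl(pos=100, ac=1000, an=10000, dpf=0.99)]  # af 0.1
        rows = burden_table(calls, controls, n_controls=1000)
        assert rows[0].p_dom > 0.5

    def test_empty_cohort_gives_empty_table(self):
        assert burden_table({}, [], 1000) == []

    def test_depth_failed_controls_excluded(self):
        v = make_passing_variant(gene="G", pos=100)
        calls = {"S1": [make_call(v)], "S2": []}
        bad = [_ctl(pos=100, ac=5000, an=10000, dpf=0.5)]
        rows = burden_table(calls, bad, n_controls=1000)
        # control carriers fall to zero because the only site fails QC
        assert rows[0].n_control_carriers_dom == 0

    def test_rows_sorted_by_dominant_p(self):
        calls, controls, n = generate_null_burden(n_genes=120, seed=3)
        rows = burden_table(calls, controls, n)
        ps = [r.p_dom for r in rows]
        assert ps == sorted(ps)
        assert all(r.p_dom_bonferroni >= r.p_dom for r in rows)

    def test_null_calibration_small(self):
        """On matched null data, few genes reach nominal significance."""
        calls, controls, n = generate_null_burden(n_genes=400, seed=1)
        rows = burden_table(calls, controls, n)
        frac = sum(1 for r in rows if r.p_dom < 0.05) / 400
        assert frac <= 0.07
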