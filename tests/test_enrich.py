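"""Term over-representation, p-value adjustment, proportion comparison."""

import math
import shutil
import subprocess
from fractions import Fraction

import numpy as np
import pytest

from cosegscan import (
    TermGeneSet,
    adjust_pvalues,
    common_terms,
    hypergeometric_enrichment,
    proportion_increase_test,
    read_gmt,
    write_gmt,
)


def genes(prefix, n):
    return [f"{prefix}{i}" for i in range(n)]


def term(term_id, members, name="t"):
    return TermGeneSet(term_id, name, frozenset(members))


def exact_upper_tail(N, K, n, k):
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    total = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    )
    return Fraction(total, math.comb(N, n))


class TestGmt:
    def test_round_trip(self, tmp_path):
        terms = [
            term("GO:0001", {"A", "B", "C"}),
            term("REAC:77", {"B", "D"}),
        ]
        p = tmp_path / "t.gmt"
        write_gmt(terms, p)
        back = read_gmt(p)
        assert back == terms
        assert back[0].source_tag == "GO_MF"
        assert back[1].source_tag == "REAC"

    def test_duplicate_term_id_rejected(self, tmp_path):
        p = tmp_path / "d.gmt"
        p.write_text("GO:1\tx\tA\tB\nGO:1\ty\tC\tD\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "m.gmt"
        p.write_text("GO:1\tonly-name\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(p)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TermGeneSet("GO:1", "x", frozenset())


class TestHypergeometricEnrichment:
    def test_fully_contained_query_is_extreme(self):
        universe = genes("u", 20000)
        query = universe[:10]
        rows = hypergeometric_enrichment(query, [term("GO:1", query)], universe)
        assert rows[0].p_raw == pytest.approx(
            float(exact_upper_tail(20000, 10, 10, 10)), rel=1e-9
        )
        assert rows[0].p_raw < 1e-30

    def test_disjoint_query_gives_p_one(self):
        universe = genes("u", 100)
        rows = hypergeometric_enrichment(
            universe[:5], [term("GO:1", universe[50:60])], universe
        )
        assert rows[0].p_raw == 1.0
        assert rows[0].k == 0

    def test_term_equal_to_universe_gives_p_one(self):
        universe = genes("u", 30)
        rows = hypergeometric_enrichment(universe[:7], [term("GO:1", universe)], universe)
        assert rows[0].p_raw == pytest.approx(1.0, abs=1e-12)

    def test_default_universe_is_annotated_genes(self):
        t1 = term("GO:1", {"A", "B"})
        t2 = term("GO:2", {"B", "C", "D"})
        rows = hypergeometric_enrichment(["A", "B"], [t1, t2])
        # universe = {A,B,C,D}; term GO:1 overlap 2 of 2 -> p = C(2,2)C(2,0)/C(4,2)
        assert rows[0].term.term_id == "GO:1"
        assert rows[0].p_raw == pytest.approx(1 / 6, rel=1e-12)

    def test_query_outside_universe_dropped(self):
        universe = genes("u", 10)
        rows = hypergeometric_enrichment(
            universe[:3] + ["NOT_THERE"], [term("GO:1", universe[:3])], universe
        )
        assert rows[0].k == 3

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty gene universe"):
            hypergeometric_enrichment(["A"], [], universe=[])

    def test_exhaustive_small_universe_oracle(self):
        """End-to-end agreement with exact enumeration for small universes."""
        for N in (4, 7, 11, 16):
            universe = genes("u", N)
            for K in range(1, N + 1):
                t = term("GO:1", universe[:K])
                for n in range(0, N + 1):
                    query = universe[N - n:]
                    rows = hypergeometric_enrichment(query, [t], universe)
                    k = len(set(universe[:K]) & set(query))
                    expected = float(exact_upper_tail(N, K, n, k)) if k > 0 else 1.0
                    assert rows[0].p_raw == pytest.approx(expected, abs=1e-12)


class TestAdjustPvalues:
    def test_bonferroni_single_row_unchanged(self):
        rows = hypergeometric_enrichment(
            genes("u", 10)[:3], [term("GO:1", genes("u", 10)[:3])], genes("u", 10)
        )
        adjust_pvalues(rows, "bonferroni")
        assert rows[0].p_adj == rows[0].p_raw

    def test_bonferroni_scales_by_m(self):
        universe = genes("u", 40)
        terms = [term(f"GO:{i}", universe[i : i + 10]) for i in range(3)]
        rows = hypergeometric_enrichment(universe[:10], terms, universe)
        adjust_pvalues(rows, "bonferroni")
        for r in rows:
            assert r.p_adj == pytest.approx(min(1.0, r.p_raw * 3), rel=1e-12)

    def test_bh_step_up_arithmetic(self):
        """Hand-checked BH on p = (0.01, 0.04, 0.9) -> (0.03, 0.06, 0.9)."""
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([0.01, 0.04, 0.9], method="fdr_bh")
        assert list(adj) == pytest.approx([0.03, 0.06, 0.9], rel=1e-12)

    def test_adjusted_rank_monotone(self):
        universe = genes("u", 60)
        rng = np.random.default_rng(0)
        terms = [
            term(f"GO:{i}", rng.choice(universe, size=12, replace=False))
            for i in range(15)
        ]
        query = universe[:12]
        for method in ("bh", "bonferroni"):
            rows = adjust_pvalues(
                hypergeometric_enrichment(query, terms, universe), method
            )
            adj = [r.p_adj for r in rows]  # rows sorted by p_raw
            assert adj == sorted(adj)
            assert all(r.p_adj >= r.p_raw - 1e-15 for r in rows)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([], "holmes")


class TestCommonTerms:
    def _rows(self, sig_ids, universe, query):
        terms = [term(tid, universe[:6]) for tid in sig_ids]
        return hypergeometric_enrichment(query, terms, universe)

    def test_identical_inputs_share_all_terms(self):
        universe = genes("u", 200)
        rows = self._rows(["GO:1", "GO:2"], universe, universe[:6])
        shared = common_terms(rows, rows, alpha=0.01)
        assert [t.term_id for t, _, _ in shared] == ["GO:1", "GO:2"]
        assert all(ca == cb for _, ca, cb in shared)

    def test_disjoint_significant_terms_share_nothing(self):
        universe = genes("u", 200)
        a = self._rows(["GO:1"], universe, universe[:6])
        b = self._rows(["GO:2"], universe, universe[:6])
        assert common_terms(a, b, alpha=0.01) == []

    def test_constructed_six_shared_terms(self):
        """Two analyses built to share exactly six significant terms."""
        universe = genes("u", 500)
        shared_ids = [f"GO:S{i}" for i in range(6)]
        a_only = ["REAC:A1", "REAC:A2"]
        b_only = ["KEGG:B1"]
        query_a = universe[:8]
        query_b = universe[4:14]
        both = sorted(set(query_a) & set(query_b))  # genes u4..u7
        terms_a = {tid: term(tid, both) for tid in shared_ids + a_only}
        terms_b = {tid: term(tid, both) for tid in shared_ids + b_only}
        rows_a = hypergeometric_enrichment(query_a, list(terms_a.values()), universe)
        rows_b = hypergeometric_enrichment(query_b, list(terms_b.values()), universe)
        shared = common_terms(rows_a, rows_b, alpha=0.01)
        assert sorted(t.term_id for t, _, _ in shared) == sorted(shared_ids)


class TestProportionIncrease:
    def test_equal_proportions_not_significant(self):
        assert proportion_increase_test(5, 50, 5, 50) >= 0.5

    def test_large_increase_significant(self):
        assert proportion_increase_test(1, 100, 30, 100) < 1e-6

    def test_degenerate_zero_counts(self):
        assert proportion_increase_test(0, 10, 0, 10) == 1.0

    def test_frozen_value_from_stated_formula(self):
        """Hand computation: p=31/200, cc=0.01, z=(0.29-0.01)/se."""
        pooled = 31 / 200
        se = math.sqrt(pooled * (1 - pooled) * (1 / 100 + 1 / 100))
        z = (0.30 - 0.01 - 0.01) / se
        from scipy.stats import norm

        assert proportion_increase_test(1, 100, 30, 100) == pytest.approx(
            float(norm.sf(z)), rel=1e-12
        )

    def test_direction_antisymmetric(self):
        p_fwd = proportion_increase_test(2, 50, 20, 50)
        p_rev = proportion_increase_test(20, 50, 2, 50)
        assert p_fwd < 0.05 < p_rev

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            proportion_increase_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            proportion_increase_test(11, 10, 1, 10)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_against_r_prop_test(self):
        """Cross-check against R's prop.test where its continuity correction
        is not capped (|p1 - p2| > cc)."""
        cases = [(1, 100, 30, 100), (3, 60, 20, 60), (5, 200, 40, 150)]
        script = ";".join(
            f"cat(prop.test(c({ka},{kb}), c({na},{nb}), "
            f"alternative='less', correct=TRUE)$p.value, '\\n')"
            for ka, na, kb, nb in cases
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        ).stdout.split()
        for (ka, na, kb, nb), r_p in zip(cases, map(float, out)):
            ours = proportion_increase_test(ka, na, kb, nb)
            assert ours == pytest.approx(r_p, rel=1e-4)
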