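"""Region aggregation, chi-squared testing, BH-FDR, DMR/DMG calling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from ovulemeth.dmr import (aggregate, bh_fdr, call_dmrs, chi2_test,
                           crosstab_cgi, crosstab_types, map_dmgs,
                           smoothed_ratio)
from ovulemeth.elements import GenomeElement
from ovulemeth.methcall import ContextIndex, MethCounts


def _counts_for(genome, spec):
    counts = MethCounts({c: len(s) for c, s in genome.items()})
    for (chrom, pos), (m, u) in spec.items():
        counts.meth[chrom][pos] = m
        counts.unmeth[chrom][pos] = u
    return counts


class TestAggregate:
    GENOME = {"c": "ACGACGACGACGACGACG" * 60}

    def test_counts_add_and_ratio(self):
        ci = ContextIndex(self.GENOME)
        el = GenomeElement("e", "c", 0, 9, "exon")
        # Watson CG cytosines at 1, 4, 7
        a = _counts_for(self.GENOME, {("c", 1): (3, 7), ("c", 4): (2, 8),
                                      ("c", 7): (0, 0)})
        b = _counts_for(self.GENOME, {("c", 1): (5, 5), ("c", 4): (5, 5),
                                      ("c", 7): (5, 5)})
        df = aggregate([el], ci, a, b, min_covered_sites=1, min_total_calls=1)
        row = df.iloc[0]
        assert (row["m_a"], row["u_a"]) == (5, 15)
        assert row["m_a"] / (row["m_a"] + row["u_a"]) == 0.25

    def test_zero_coverage_untestable(self):
        ci = ContextIndex(self.GENOME)
        el = GenomeElement("e", "c", 0, 50, "exon")
        empty = MethCounts({"c": len(self.GENOME["c"])})
        df = aggregate([el], ci, empty, empty)
        assert not df.iloc[0]["testable"]

    def test_matches_per_base_brute_force(self, rng):
        genome = {"c": rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                                  size=1000).tobytes().decode()}
        ci = ContextIndex(genome)
        a = MethCounts({"c": 1000})
        b = MethCounts({"c": 1000})
        for counts in (a, b):
            counts.meth["c"][:] = rng.integers(0, 10, 1000)
            counts.unmeth["c"][:] = rng.integers(0, 10, 1000)
        el = GenomeElement("e", "c", 100, 900, "exon")
        df = aggregate([el], ci, a, b)
        # oracle: walk every base, include classifiable cytosines only
        m_a = u_a = 0
        for pos in range(100, 900):
            if ci.codes["c"][pos] >= 0:
                m_a += a.meth["c"][pos]
                u_a += a.unmeth["c"][pos]
        assert (df.iloc[0]["m_a"], df.iloc[0]["u_a"]) == (m_a, u_a)


class TestChi2:
    def test_hand_computed_example(self):
        # expected cells (70, 30, 70, 30): sum (O-E)^2/E = 38.095...
        stat, p, method = chi2_test(90, 10, 50, 50)
        assert method == "chi2"
        assert stat == pytest.approx(400 * (2 / 70 + 2 / 30), abs=1e-9)
        assert stat == pytest.approx(38.095, abs=1e-3)

    def test_identical_proportions(self):
        stat, p, _ = chi2_test(50, 50, 50, 50)
        assert stat == 0.0 and p == 1.0

    def test_p_monotone_in_effect(self):
        _, p1, _ = chi2_test(90, 10, 50, 50)
        _, p2, _ = chi2_test(99, 1, 50, 50)
        assert p2 < p1

    def test_zero_marginal_degenerate(self):
        stat, p, method = chi2_test(0, 10, 0, 20)
        assert (stat, p, method) == (0.0, 1.0, "degenerate")

    def test_sparse_table_falls_back_to_fisher(self):
        stat, p, method = chi2_test(3, 1, 1, 4)
        assert method == "fisher"
        assert p == pytest.approx(
            sps.fisher_exact([[3, 1], [1, 4]])[1])

    def test_agrees_with_scipy_on_random_tables(self, rng):
        for _ in range(1000):
            a, b, c, d = rng.integers(5, 500, size=4)
            stat, p, method = chi2_test(a, b, c, d)
            if method != "chi2":
                continue
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestBH:
    def test_hand_recursion_fixture(self):
        q = bh_fdr([0.001, 0.004, 0.03])
        assert q == pytest.approx([0.003, 0.006, 0.03])

    def test_all_equal_pass_through(self):
        assert bh_fdr([0.5, 0.5, 0.5]) == pytest.approx([0.5, 0.5, 0.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_q_at_least_p_and_order_invariant(self, pvals):
        q = bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0)
        perm = np.random.default_rng(0).permutation(len(pvals))
        q_perm = bh_fdr(np.asarray(pvals)[perm])
        assert np.allclose(np.sort(q), np.sort(q_perm))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(500)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), q_ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _region_df(rows):
    base = {"chrom": "c", "start": 0, "end": 100, "element_type": "exon",
            "gene_id": None, "cpg_class": None, "rank": None, "n_sites": 10,
            "covered_a": 10, "covered_b": 10, "testable": True}
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d.update(r)
        d.setdefault("element_id", f"e{i}")
        d["start"] = i * 100
        d["end"] = i * 100 + 100
        out.append(d)
    return pd.DataFrame(out)


class TestCallDmrs:
    def test_fold_change_uses_smoothed_ratios(self):
        df = _region_df([{"m_a": 90, "u_a": 10, "m_b": 30, "u_b": 70}])
        out = call_dmrs(df, q_max=0.01, fc_min=2.0)
        r_a, r_b = smoothed_ratio(90, 10), smoothed_ratio(30, 70)
        assert out.iloc[0]["fold_change"] == pytest.approx(r_a / r_b)
        assert out.iloc[0]["direction"] == "hyper"
        assert out.iloc[0]["is_dmr"]

    def test_significant_but_small_fold_not_a_dmr(self):
        df = _region_df([{"m_a": 5000, "u_a": 5000, "m_b": 3000, "u_b": 7000}])
        out = call_dmrs(df, q_max=0.001, fc_min=2.0)
        assert out.iloc[0]["q"] < 1e-6          # overwhelming significance
        assert out.iloc[0]["fold_change"] < 2.0  # 0.5 vs 0.3 ratio
        assert not out.iloc[0]["is_dmr"]

    def test_label_swap_flips_every_direction(self):
        rng = np.random.default_rng(1)
        rows = [{"m_a": int(m), "u_a": int(u), "m_b": int(m2), "u_b": int(u2)}
                for m, u, m2, u2 in rng.integers(10, 300, size=(30, 4))]
        fwd = call_dmrs(_region_df(rows), interest="a", reference="b")
        rev = call_dmrs(_region_df(rows), interest="b", reference="a")
        fwd = fwd.set_index("element_id")
        rev = rev.set_index("element_id")
        for el in fwd.index:
            f, r = fwd.loc[el], rev.loc[el]
            assert f["q"] == pytest.approx(r["q"], rel=1e-12, abs=1e-300)
            assert f["fold_change"] == pytest.approx(r["fold_change"])
            if f["direction"] != "none":
                assert {f["direction"], r["direction"]} == {"hyper", "hypo"}
            assert f["is_dmr"] == r["is_dmr"]

    def test_untestable_elements_get_no_q(self):
        df = _region_df([{"m_a": 0, "u_a": 0, "m_b": 0, "u_b": 0,
                          "testable": False},
                         {"m_a": 200, "u_a": 20, "m_b": 30, "u_b": 200}])
        out = call_dmrs(df).set_index("element_id")
        assert np.isnan(out.loc["e0", "q"])
        assert not out.loc["e0", "is_dmr"]

    def test_interest_equals_reference_rejected(self):
        with pytest.raises(ValueError):
            call_dmrs(_region_df([{"m_a": 1, "u_a": 1, "m_b": 1, "u_b": 1}]),
                      interest="a", reference="a")

    def test_both_ratios_zero_never_a_dmr(self):
        df = _region_df([{"m_a": 0, "u_a": 500, "m_b": 0, "u_b": 40}])
        out = call_dmrs(df)
        assert out.iloc[0]["fold_change"] < 2.0
        assert not out.iloc[0]["is_dmr"]


class TestDmgsAndCrosstabs:
    def _dmr_table(self):
        rows = [
            {"element_id": "g1:prom", "element_type": "promoter",
             "gene_id": "g1", "direction": "hyper", "is_dmr": True},
            {"element_id": "g2:exon1", "element_type": "exon",
             "gene_id": "g2", "direction": "hyper", "is_dmr": True},
            {"element_id": "g2:intron1", "element_type": "intron",
             "gene_id": "g2", "direction": "hypo", "is_dmr": True},
            {"element_id": "ig:1", "element_type": "intergenic",
             "gene_id": None, "direction": "hypo", "is_dmr": True},
            {"element_id": "g3:prom", "element_type": "promoter",
             "gene_id": "g3", "direction": "hypo", "is_dmr": False},
        ]
        return pd.DataFrame(rows)

    def test_single_promoter_dmr_makes_a_dmg(self):
        dmgs = map_dmgs(self._dmr_table()).set_index("gene_id")
        assert dmgs.loc["g1", "direction"] == "hyper"
        assert "g3" not in dmgs.index  # not a DMR
        assert "ig:1" not in dmgs.index

    def test_hyper_hypo_tie_is_mixed(self):
        dmgs = map_dmgs(self._dmr_table()).set_index("gene_id")
        assert dmgs.loc["g2", "direction"] == "mixed"

    def test_type_crosstab_conserves_total(self):
        tab = crosstab_types(self._dmr_table())
        assert tab["total"].sum() == 4

    def test_cgi_crosstab_totals_are_column_sums(self):
        labels = {"g1:prom": "CGI", "g2:exon1": "CGI_shore",
                  "g2:intron1": None, "ig:1": "CGI_shore"}
        tab = crosstab_cgi(self._dmr_table(), labels).set_index("element_type")
        assert tab.loc["Total", "CGI"] == tab.drop("Total")["CGI"].sum() == 1
        assert tab.loc["Total", "CGI_shore"] == 2
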