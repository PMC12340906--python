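"""Bulk/pseudobulk transcriptomics: TMM, moderated t, consistency filters."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from methylsubtypes.rnaseq import (
    cross_cohort_deg_filter,
    de_moderated,
    low_expression_filter,
    pseudobulk,
    state_deg_selection,
    tmm_factors,
    tmm_logcpm,
)


class TestLowExpressionFilter:
    def test_rule_table(self):
        # 10 samples: gene low in 9 (90% > 80%) dropped; low in exactly 8 kept
        counts = pd.DataFrame(
            {
                f"s{i}": [0 if i < 9 else 50, 0 if i < 8 else 50, 100]
                for i in range(10)
            },
            index=["low90", "low80", "high"],
        )
        kept = low_expression_filter(counts)
        assert kept == ["low80", "high"]

    def test_always_expressed_kept(self, rng):
        counts = pd.DataFrame(rng.integers(10, 100, size=(5, 8)))
        assert len(low_expression_filter(counts)) == 5


class TestTmm:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(0, 500, size=200)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        np.testing.assert_allclose(tmm_factors(counts), 1.0, atol=1e-9)

    def test_pure_depth_scaling_composition_invariant(self, rng):
        col = rng.integers(10, 500, size=300)
        counts = pd.DataFrame({"a": col, "b": col * 2, "c": col})
        f = tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0, atol=1e-9)
        logcpm, _ = tmm_logcpm(counts)
        np.testing.assert_allclose(logcpm["a"], logcpm["b"], atol=0.05)

    def test_six_gene_toy_matches_hand_trimmed_mean(self):
        """Two libraries, 6 genes; the doubly-trimmed weighted M-mean is
        computed by hand for the non-reference library."""
        ref = np.array([100.0, 200.0, 300.0, 400.0, 500.0, 600.0])
        obs = np.array([210.0, 380.0, 660.0, 830.0, 1000.0, 1500.0])  # distinct ratios
        counts = pd.DataFrame({"ref": ref, "obs": obs})
        lib_r, lib_o = ref.sum(), obs.sum()
        po, pr = obs / lib_o, ref / lib_r
        m = np.log2(po / pr)
        w = (lib_o - obs) / (lib_o * obs) + (lib_r - ref) / (lib_r * ref)
        # n=6: M-trim 30% drops rank 1 and 6; A-trim 5% drops none
        order = np.argsort(m)
        keep = order[1:-1]
        f_obs = 2 ** ((m[keep] / w[keep]).sum() / (1 / w[keep]).sum())
        f = tmm_factors(counts)
        expected = np.array([1.0, f_obs])
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(f.to_numpy(), expected, rtol=1e-10)

    def test_matches_edger_on_random_counts(self, rng):
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.1, size=(300, 5)),
            columns=[f"s{i}" for i in range(5)],
        )
        counts = counts.loc[low_expression_filter(counts, min_count=1, max_frac=0.5)]
        csv = ";".join(",".join(map(str, row)) for row in counts.to_numpy())
        script = (
            "suppressMessages(library(edgeR));"
            f"m <- do.call(rbind, lapply(strsplit(strsplit('{csv}', ';')[[1]], ','), as.numeric));"
            "f <- calcNormFactors(DGEList(counts=m), method='TMM');"
            "cat(f$samples$norm.factors)"
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=180
            )
            ref = np.array(list(map(float, out.stdout.split())))
        except (FileNotFoundError, ValueError):
            pytest.skip("Rscript/edgeR unavailable")
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(), ref, rtol=1e-4)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [0, 0], "b": [1, 2]})
        with pytest.raises(ValueError):
            tmm_factors(counts)


def _de_fixture(rng, n_per=20, n_genes=300, lfc=0.0):
    n = 2 * n_per
    samples = pd.DataFrame(
        {"subtype": ["S1"] * n_per + ["HC"] * n_per},
        index=[f"s{i}" for i in range(n)],
    )
    x = rng.normal(5.0, 1.0, size=(n_genes, n))
    x[0, :n_per] += lfc
    logcpm = pd.DataFrame(
        x, index=[f"g{i}" for i in range(n_genes)], columns=samples.index
    )
    return logcpm, samples


class TestDeModerated:
    def test_d0_zero_equals_ordinary_t(self, rng):
        logcpm, samples = _de_fixture(rng, lfc=1.0)
        from scipy.stats import ttest_ind

        res = de_moderated(logcpm, samples, ("S1", "HC"), d0_override=0)
        t_ref = ttest_ind(
            logcpm.iloc[0, :20], logcpm.iloc[0, 20:], equal_var=True
        )
        assert res["t"].iloc[0] == pytest.approx(t_ref.statistic, rel=1e-10)
        assert res["p"].iloc[0] == pytest.approx(t_ref.pvalue, rel=1e-8)

    def test_d0_infinite_pools_variance(self, rng):
        logcpm, samples = _de_fixture(rng)
        res = de_moderated(logcpm, samples, ("S1", "HC"), d0_override=np.inf)
        assert res["se"].nunique() == 1  # common variance across genes

    def test_null_pvalues_uniform(self, rng):
        logcpm, samples = _de_fixture(rng, n_genes=2000)
        res = de_moderated(logcpm, samples, ("S1", "HC"))
        assert kstest(res["p"], "uniform").pvalue > 0.01

    def test_planted_gene_detected(self, rng):
        logcpm, samples = _de_fixture(rng, lfc=2.0)
        res = de_moderated(logcpm, samples, ("S1", "HC"))
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.7)
        assert res["p"].iloc[0] < 1e-6


class TestCrossCohortFilter:
    def _tables(self, rows):
        """rows: gene -> (p per cohort, lfc per cohort)."""
        cohorts = ["c1", "c2", "c3"]
        out = {}
        for i, c in enumerate(cohorts):
            out[c] = pd.DataFrame(
                {
                    "log2fc": {g: v[1][i] for g, v in rows.items()},
                    "p": {g: v[0][i] for g, v in rows.items()},
                }
            )
        return out

    def test_rule_table(self):
        rows = {
            "sel": ((0.01, 0.02, 0.03), (0.7, 0.2, 0.1)),
            "signflip": ((0.01, 0.01, 0.01), (0.7, -0.2, 0.1)),
            "p_fail": ((0.01, 0.2, 0.01), (0.7, 0.7, 0.7)),
            "fc_fail": ((0.01, 0.01, 0.01), (0.2, 0.3, 0.1)),
        }
        tab = cross_cohort_deg_filter(self._tables(rows))
        assert tab.loc["sel", "selected"]
        assert not tab.loc["signflip", "selected"]
        assert not tab.loc["p_fail", "selected"]
        assert not tab.loc["fc_fail", "selected"]
        assert tab.loc["signflip", "pass_p_all"]
        assert not tab.loc["signflip", "consistent_sign"]

    def test_filter_monotone_in_thresholds(self, rng):
        rows = {
            f"g{i}": (
                tuple(rng.uniform(0, 0.2, 3)),
                tuple(rng.normal(0, 0.8, 3)),
            )
            for i in range(50)
        }
        tabs = self._tables(rows)
        strict = set(
            cross_cohort_deg_filter(tabs, p_thresh=0.03, fc_thresh=2.0)
            .query("selected")
            .index
        )
        loose = set(
            cross_cohort_deg_filter(tabs, p_thresh=0.05, fc_thresh=1.5)
            .query("selected")
            .index
        )
        assert strict <= loose

    def test_single_cohort_rejected(self):
        with pytest.raises(ValueError):
            cross_cohort_deg_filter({"c1": pd.DataFrame({"log2fc": [], "p": []})})


class TestPseudobulk:
    def _cells(self):
        counts = pd.DataFrame(
            {
                "c1": [1, 2, 0],
                "c2": [0, 1, 3],
                "c3": [5, 0, 1],
                "c4": [2, 2, 2],
            },
            index=["g1", "g2", "g3"],
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["sA", "sA", "sB", "sB"],
                "state": ["MG0", "MG0", "MG0", "MG1"],
            },
            index=counts.columns,
        )
        return counts, meta

    def test_exact_integer_sums(self):
        counts, meta = self._cells()
        pb = pseudobulk(
            counts,
            meta,
            {"sA": "S1", "sB": "HC"},
            ["S1", "HC"],
            min_cells=1,
            min_depth=1,
        )
        np.testing.assert_array_equal(
            pb.counts["MG0"]["sA"].to_numpy(), [1, 3, 3]
        )
        np.testing.assert_array_equal(
            pb.counts["MG0"]["sB"].to_numpy(), [5, 0, 1]
        )

    def test_sum_invariant_under_cell_order(self):
        counts, meta = self._cells()
        order = ["c3", "c1", "c4", "c2"]
        pb1 = pseudobulk(counts, meta, {"sA": "S1", "sB": "HC"}, ["S1"], 1, 1)
        pb2 = pseudobulk(
            counts[order], meta.loc[order], {"sA": "S1", "sB": "HC"}, ["S1"], 1, 1
        )
        pd.testing.assert_frame_equal(pb1.counts["MG0"], pb2.counts["MG0"])

    def test_state_below_min_cells_excluded_with_log(self):
        counts, meta = self._cells()
        pb = pseudobulk(
            counts,
            meta,
            {"sA": "S1", "sB": "HC"},
            ["S1", "HC"],
            min_cells=2,
            min_depth=1,
        )
        assert not pb.included["MG1"]
        assert any(entry[0] == "MG1" for entry in pb.excluded_log)


class TestStateDegSelection:
    def test_selection_rules(self):
        def tab(ps):
            return pd.DataFrame({"p": ps}, index=["gA", "gB", "gC"])

        per_state = {
            "MG0": {
                # gA: subtype split + vs-control in one subtype -> selected
                # gB: subtype split only -> rejected
                # gC: control-only signal -> rejected
                "s1_vs_s2": tab([0.001, 0.01, 0.5]),
                "s1_vs_hc": tab([0.02, 0.6, 0.01]),
                "s2_vs_hc": tab([0.7, 0.8, 0.001]),
            },
            "MG1": {
                "s1_vs_s2": tab([0.5, 0.01, 0.01]),
                "s1_vs_hc": tab([0.01, 0.9, 0.04]),
                "s2_vs_hc": tab([0.01, 0.9, 0.9]),
            },
        }
        per_state_sel, pooled = state_deg_selection(per_state)
        assert per_state_sel["MG0"] == ["gA"]
        assert per_state_sel["MG1"] == ["gC"]
        assert pooled == ["gA", "gC"]

    def test_constructed_truth_recovered_exactly(self, rng):
        genes = [f"g{i}" for i in range(40)]
        positives = set(rng.choice(genes, 10, replace=False))
        ps = {}
        for key in ("s1_vs_s2", "s1_vs_hc", "s2_vs_hc"):
            ps[key] = pd.DataFrame(
                {"p": [0.001 if g in positives else 0.5 for g in genes]},
                index=genes,
            )
        sel, pooled = state_deg_selection({"MG0": ps})
        assert set(pooled) == positives
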