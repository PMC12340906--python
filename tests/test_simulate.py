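"""Ground-truth recovery and determinism of the synthetic-cohort generators."""

import numpy as np
import pandas as pd
import pytest

from methylsubtypes.cluster import cluster_kmeans, nmi
from methylsubtypes.overlap import fisher_overlap
from methylsubtypes.simulate import (
    ConfigurationError,
    SimulationConfig,
    generate_celltype_panels,
    generate_expression_data,
    generate_methylation_cohorts,
    generate_sc_counts,
    generate_summary_stats,
)


def _small(seed=3, **kw):
    base = dict(
        n_load_per_cohort=60,
        n_hc_per_cohort=24,
        n_probes=600,
        n_genes=300,
        n_sc_genes=150,
        n_sc_samples=18,
        cells_per_state=6,
        n_states=3,
        n_included_states=2,
        sc_degs_per_state=5,
        n_regions_per_scenario=1,
        panel_size=60,
        seed=seed,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"frac_subtype_cpgs": 1.2},
            {"frac_subtype_cpgs": -0.1},
            {"n_shared_subtypes": 0},
            {"platform_mask_fracs": {2: 0.0}},
            {"delta_beta": 0.7},
        ],
    )
    def test_invalid_fractions_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            _small(**kw)


class TestMethylation:
    def test_same_seed_identical_outputs(self):
        b1, s1, t1 = generate_methylation_cohorts(_small(seed=11))
        b2, s2, t2 = generate_methylation_cohorts(_small(seed=11))
        for x, y in zip(b1, b2):
            pd.testing.assert_frame_equal(x.values, y.values)
        for x, y in zip(s1, s2):
            pd.testing.assert_frame_equal(x, y)
        assert t1.subtype_of_sample == t2.subtype_of_sample

    def test_beta_in_open_unit_interval_and_mask(self):
        betas, _, _ = generate_methylation_cohorts(_small())
        for b in betas:
            arr = b.values.to_numpy()
            assert arr.min() > 0.0 and arr.max() < 1.0
        assert betas[2].platform == "450K-like"
        assert betas[2].values.shape[0] < betas[0].values.shape[0]
        assert set(betas[2].probe_ids) <= set(betas[0].probe_ids)

    def test_planted_beta_shift_recovered_by_group_means(self):
        cfg = _small(n_load_per_cohort=150, n_probes=2000)
        betas, sheets, truth = generate_methylation_cohorts(cfg)
        diffs = []
        for b in betas[:2]:  # unmasked cohorts
            lab = pd.Series(
                {s: truth.subtype_of_sample[s] for s in b.sample_ids}
            )
            for g in ("S1", "S2"):
                other = "S2" if g == "S1" else "S1"
                sub = b.values.loc[truth.causal_cpgs[g]]
                d = (
                    sub[lab[lab == g].index].mean(axis=1)
                    - sub[lab[lab == other].index].mean(axis=1)
                ).abs()
                diffs.append(d.mean())
        assert np.mean(diffs) == pytest.approx(cfg.delta_beta, abs=0.02)

    def test_no_signal_clustering_is_chance_level(self):
        cfg = _small(delta_beta=0.0, cohort_specific_cluster=False)
        betas, sheets, truth = generate_methylation_cohorts(cfg)
        b = betas[0]
        lab = np.array(
            [truth.subtype_of_sample[s] for s in b.sample_ids if truth.subtype_of_sample[s] != "HC"]
        )
        load = [s for s in b.sample_ids if truth.subtype_of_sample[s] != "HC"]
        x = b.values[load].T
        labels = cluster_kmeans(x, 2, seed=0)
        assert nmi(labels, lab) < 0.1

    def test_covariate_effects_present_on_modelling_scale(self):
        cfg = _small(covariate_effects={"sex": 0.8})
        betas, sheets, _ = generate_methylation_cohorts(cfg)
        logit = np.log(betas[0].values / (1 - betas[0].values))
        sex = sheets[0]["sex"].to_numpy()
        r = np.array([np.corrcoef(row, sex)[0, 1] for row in logit.to_numpy()])
        # per-probe random weights: many probes should show a clear sex effect
        assert np.quantile(np.abs(r), 0.9) > 0.3


class TestExpression:
    def test_planted_log2fc_recovered(self):
        cfg = _small(n_load_per_cohort=100, log2fc=1.0)
        betas, sheets, truth = generate_methylation_cohorts(cfg)
        counts = generate_expression_data(cfg, truth)
        c0 = counts[0]
        lab = pd.Series({s: truth.subtype_of_sample[s] for s in c0.columns})
        cpm = c0 / c0.sum(axis=0) * 1e6
        ratios = []
        for g in truth.causal_genes["S1"]:
            m1 = cpm.loc[g, lab[lab == "S1"].index].mean()
            m0 = cpm.loc[g, lab[lab == "HC"].index].mean()
            hi, lo = max(m1, m0), min(m1, m0)
            if lo > 0:
                ratios.append(hi / lo)
        assert np.median(ratios) == pytest.approx(2.0, rel=0.25)

    def test_consistent_sign_across_cohorts(self):
        cfg = _small()
        _, _, truth = generate_methylation_cohorts(cfg)
        counts = generate_expression_data(cfg, truth)
        lab = pd.Series(truth.subtype_of_sample)
        for g in truth.causal_genes["S1"][:10]:
            signs = []
            for c in counts:
                cols = c.columns
                m1 = c.loc[g, [s for s in cols if lab[s] == "S1"]].mean()
                m0 = c.loc[g, [s for s in cols if lab[s] == "HC"]].mean()
                signs.append(np.sign(m1 - m0))
            assert len(set(signs)) == 1

    def test_determinism(self):
        cfg = _small(seed=9)
        _, _, t1 = generate_methylation_cohorts(cfg)
        _, _, t2 = generate_methylation_cohorts(cfg)
        a = generate_expression_data(cfg, t1)
        b = generate_expression_data(cfg, t2)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestSingleCell:
    def test_structure_and_determinism(self):
        cfg = _small(seed=5)
        _, _, truth = generate_methylation_cohorts(cfg)
        c1, m1 = generate_sc_counts(cfg, truth)
        c2, m2 = generate_sc_counts(cfg, truth)
        pd.testing.assert_frame_equal(c1, c2)
        assert set(m1.columns) == {"sample_id", "state", "group"}
        # small states carry fewer cells per sample than included states
        per_state = m1.groupby("state").size()
        small = [f"MG{s}" for s in range(cfg.n_included_states, cfg.n_states)]
        big = [f"MG{s}" for s in range(cfg.n_included_states)]
        assert per_state[small].max() < per_state[big].min()

    def test_planted_state_degs_by_group_means(self):
        cfg = _small(seed=5, log2fc=1.5)
        _, _, truth = generate_methylation_cohorts(cfg)
        counts, meta = generate_sc_counts(cfg, truth)
        state0 = meta.index[meta["state"] == "MG0"]
        sub = counts[state0]
        grp = meta.loc[state0, "group"]
        genes = truth.sc_causal_genes["MG0:S1"]
        m_s1 = sub.loc[genes, grp[grp == "S1"].index].mean(axis=1)
        m_hc = sub.loc[genes, grp[grp == "HC"].index].mean(axis=1)
        assert (m_s1 / m_hc).median() == pytest.approx(2.0**1.5, rel=0.3)


class TestPanels:
    def test_tiers_nested_and_planted_or_recovered(self):
        cfg = _small(n_probes=4000, panel_size=300, panel_or=8.0)
        _, _, truth = generate_methylation_cohorts(cfg)
        panels = generate_celltype_panels(cfg, truth)
        by_key = {(p.cell_type, p.specificity_level): set(p.probe_ids) for p in panels}
        for ct in {p.cell_type for p in panels}:
            assert by_key[(ct, 3)] <= by_key[(ct, 2)] <= by_key[(ct, 1)]
        causal = sorted(set().union(*truth.causal_cpgs.values()))
        enr = by_key[("microglia", 1)]
        res = fisher_overlap(
            len(causal), len(enr), len(enr & set(causal)), cfg.n_probes
        )
        assert 4.0 <= res.odds_ratio <= 16.0
        neutral = by_key[("astrocyte", 1)]
        res0 = fisher_overlap(
            len(causal), len(neutral), len(neutral & set(causal)), cfg.n_probes
        )
        assert 0.4 <= res0.odds_ratio <= 2.5


class TestSummaryStats:
    def test_scenarios_and_se_formula(self):
        cfg = _small(seed=2)
        _, _, truth = generate_methylation_cohorts(cfg)
        ss = generate_summary_stats(cfg, truth)
        scens = set(truth.coloc_scenario_of_region.values())
        assert scens == {"shared", "distinct", "null"}
        for reg, (m, g) in ss.items():
            np.testing.assert_allclose(
                m["se"],
                1.0 / np.sqrt(2 * m["maf"] * (1 - m["maf"]) * m["n"]),
                rtol=1e-12,
            )
            scen = truth.coloc_scenario_of_region[reg]
            zm, zg = (m.beta / m.se).abs(), (g.beta / g.se).abs()
            if scen == "shared":
                assert zm.idxmax() == zg.idxmax()
            if scen == "null":
                assert zm.max() < 6 and zg.max() < 6

    def test_determinism(self):
        cfg = _small(seed=4)
        _, _, t = generate_methylation_cohorts(cfg)
        a = generate_summary_stats(cfg, t)
        b = generate_summary_stats(cfg, t)
        for reg in a:
            pd.testing.assert_frame_equal(a[reg][0], b[reg][0])
            pd.testing.assert_frame_equal(a[reg][1], b[reg][1])
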