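"""EWAS regression, surrogate variables, empirical null, IVW meta-analysis."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from methylsubtypes.ewas import (
    call_dmps,
    empirical_null_correct,
    estimate_svs,
    ewas,
    inflation_lambda,
    ivw_meta,
)


def _ewas_fixture(rng, n_per=100, n_probes=200, delta=0.1, sigma=0.05):
    n = 2 * n_per
    samples = pd.DataFrame(
        {
            "subtype": ["S1"] * n_per + ["HC"] * n_per,
            "age": rng.normal(75, 8, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    base = rng.uniform(0.3, 0.7, n_probes)
    vals = rng.normal(0, sigma, size=(n_probes, n)) + base[:, None]
    vals[0, :n_per] += delta  # probe 0 carries the planted effect
    values = pd.DataFrame(
        vals, index=[f"cg{i}" for i in range(n_probes)], columns=samples.index
    )
    return values, samples


class TestEwas:
    def test_planted_effect_recovered(self, rng):
        values, samples = _ewas_fixture(rng)
        res = ewas(values, samples, ("S1", "HC"), covariates=["age"])
        assert res.loc["cg0", "effect"] == pytest.approx(0.1, abs=0.02)
        assert res.loc["cg0", "p"] < 1e-6

    def test_null_probes_uniform(self, rng):
        values, samples = _ewas_fixture(rng, n_probes=2000, delta=0.0)
        res = ewas(values, samples, ("S1", "HC"), covariates=["age"])
        assert inflation_lambda(res["p"].to_numpy()) == pytest.approx(1.0, abs=0.06)
        assert kstest(res["p"], "uniform").pvalue > 0.01

    def test_identical_groups_zero_effect(self):
        vals = pd.DataFrame(
            np.tile([0.4, 0.5, 0.6, 0.4, 0.5, 0.6], (3, 1)),
            index=["cg0", "cg1", "cg2"],
            columns=[f"s{i}" for i in range(6)],
        )
        samples = pd.DataFrame(
            {"subtype": ["S1"] * 3 + ["HC"] * 3}, index=vals.columns
        )
        res = ewas(vals, samples, ("S1", "HC"))
        np.testing.assert_allclose(res["effect"], 0.0, atol=1e-12)

    def test_small_group_rejected(self, rng):
        values, samples = _ewas_fixture(rng, n_per=2)
        with pytest.raises(ValueError):
            ewas(values, samples, ("S1", "HC"))


class TestSurrogateVariables:
    def test_hidden_batch_recovered(self, rng):
        n, p = 80, 400
        batch = np.repeat([0.0, 1.0], n // 2)
        age = rng.normal(0, 1, n)
        y = rng.normal(size=(p, n)) + np.outer(rng.normal(0, 1.2, p), batch)
        values = pd.DataFrame(y)
        sv = estimate_svs(values, age[:, None], n_sv=1)
        assert abs(np.corrcoef(sv[:, 0], batch)[0, 1]) > 0.9

    def test_svs_orthonormal(self, rng):
        values = pd.DataFrame(rng.normal(size=(100, 40)))
        sv = estimate_svs(values, rng.normal(size=(40, 2)), n_sv=3)
        np.testing.assert_allclose(sv.T @ sv, np.eye(3), atol=1e-10)

    def test_no_structure_selects_zero(self, rng):
        hits = 0
        for rep in range(10):
            values = pd.DataFrame(rng.normal(size=(300, 30)))
            sv = estimate_svs(values, rng.normal(size=(30, 1)), seed=rep)
            hits += sv.shape[1] == 0
        assert hits >= 9

    def test_too_many_svs_rejected(self, rng):
        values = pd.DataFrame(rng.normal(size=(20, 10)))
        with pytest.raises(ValueError):
            estimate_svs(values, rng.normal(size=(10, 2)), n_sv=9)


class TestInflationLambda:
    def test_uniform_p_lambda_one(self, rng):
        p = rng.uniform(size=20000)
        assert inflation_lambda(p) == pytest.approx(1.0, abs=0.03)

    def test_inflated_z_lambda(self, rng):
        from scipy.stats import norm

        z = rng.normal(0, 1.2, 50000)
        p = 2 * norm.sf(np.abs(z))
        assert inflation_lambda(p) == pytest.approx(1.44, abs=0.05)

    def test_single_p_defined(self):
        assert inflation_lambda(np.array([0.5])) == pytest.approx(1.0, abs=1e-9)


class TestEmpiricalNull:
    def test_calibrated_input_identity(self, rng):
        z = rng.normal(0, 1, 50000)
        out, en = empirical_null_correct(z, np.ones_like(z))
        assert abs(en.mu) < 0.02
        assert abs(en.sigma - 1.0) < 0.02
        assert not en.applied  # "if needed" rule leaves calibrated input alone
        np.testing.assert_allclose(out["z"], z)

    def test_biased_inflated_null_recovered(self, rng):
        z = np.concatenate(
            [
                rng.normal(0.3, 1.4, 47500),
                rng.normal(5.0, 1.0, 1250),
                rng.normal(-5.0, 1.0, 1250),
            ]
        )
        _, en = empirical_null_correct(z, np.ones_like(z))
        assert en.mu == pytest.approx(0.3, abs=0.05)
        assert en.sigma == pytest.approx(1.4, abs=0.05)
        assert en.applied

    def test_contaminated_null_estimates_stable(self, rng):
        z = np.concatenate([rng.normal(0, 1, 47500), rng.normal(5, 0.5, 2500)])
        _, en = empirical_null_correct(z, np.ones_like(z))
        assert abs(en.mu) < 0.07
        assert abs(en.sigma - 1.0) < 0.07

    def test_correction_rescales_moments(self, rng):
        z = rng.normal(0.5, 1.5, 20000)
        out, en = empirical_null_correct(z, np.ones_like(z))
        zc = out["z"].to_numpy()
        assert abs(np.median(zc)) < 0.05
        assert np.std(zc) == pytest.approx(1.0, abs=0.05)

    def test_few_probes_warns(self, rng):
        with pytest.warns(UserWarning, match="1000"):
            empirical_null_correct(rng.normal(size=100), np.ones(100))


class TestIvwMeta:
    def test_identical_studies_closed_form(self):
        eff = pd.DataFrame({"a": [0.5], "b": [0.5], "c": [0.5]}, index=["cg0"])
        se = pd.DataFrame({"a": [0.1], "b": [0.1], "c": [0.1]}, index=["cg0"])
        for method in ("fixed", "random"):
            res = ivw_meta(eff, se, method=method)
            assert res.loc["cg0", "meta_effect"] == pytest.approx(0.5, abs=1e-10)
            assert res.loc["cg0", "meta_se"] == pytest.approx(0.1 / np.sqrt(3), abs=1e-10)
            assert res.loc["cg0", "tau2"] == pytest.approx(0.0, abs=1e-10)

    def test_two_study_fixed_closed_form(self):
        eff = pd.DataFrame({"a": [1.0], "b": [3.0]}, index=["cg0"])
        se = pd.DataFrame({"a": [1.0], "b": [1.0]}, index=["cg0"])
        res = ivw_meta(eff, se, method="fixed")
        assert res.loc["cg0", "meta_effect"] == pytest.approx(2.0, abs=1e-10)
        assert res.loc["cg0", "meta_se"] == pytest.approx(np.sqrt(0.5), abs=1e-10)
        assert res.loc["cg0", "Q"] == pytest.approx(2.0, abs=1e-10)

    def test_single_study_passthrough(self):
        eff = pd.DataFrame({"a": [0.7], "b": [np.nan]}, index=["cg0"])
        se = pd.DataFrame({"a": [0.2], "b": [np.nan]}, index=["cg0"])
        res = ivw_meta(eff, se)
        assert res.loc["cg0", "n_studies"] == 1
        assert res.loc["cg0", "meta_effect"] == pytest.approx(0.7)

    def test_fixed_meta_se_not_larger_than_best_study(self, rng):
        eff = pd.DataFrame(rng.normal(size=(50, 3)))
        se = pd.DataFrame(rng.uniform(0.05, 0.5, size=(50, 3)))
        res = ivw_meta(eff, se, method="fixed")
        assert (res["meta_se"] <= se.min(axis=1) + 1e-12).all()

    def test_nonpositive_se_rejected(self):
        eff = pd.DataFrame({"a": [1.0], "b": [1.0]})
        se = pd.DataFrame({"a": [0.0], "b": [1.0]})
        with pytest.raises(ValueError):
            ivw_meta(eff, se)

    def test_random_effects_match_metafor_reml(self):
        """Cross-check tau2/effect/se against r-metafor's rma.uni REML."""
        y = [0.2, 0.5, 0.9, 0.1, 0.7]
        v = [0.04, 0.09, 0.04, 0.16, 0.09]
        script = (
            "suppressMessages(library(metafor));"
            f"r <- rma.uni(yi=c({','.join(map(str, y))}), vi=c({','.join(map(str, v))}), method='REML');"
            "cat(r$tau2, r$beta[1], r$se)"
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
            )
            tau2_r, beta_r, se_r = map(float, out.stdout.split())
        except (FileNotFoundError, ValueError):
            pytest.skip("Rscript/metafor unavailable")
        eff = pd.DataFrame([y], index=["cg0"])
        se = pd.DataFrame([np.sqrt(v)], index=["cg0"])
        res = ivw_meta(eff, se, method="random")
        assert res.loc["cg0", "tau2"] == pytest.approx(tau2_r, abs=1e-4)
        assert res.loc["cg0", "meta_effect"] == pytest.approx(beta_r, abs=1e-6)
        assert res.loc["cg0", "meta_se"] == pytest.approx(se_r, abs=1e-4)


class TestCallDmps:
    def test_boundary_strictness(self):
        m = 100
        meta = pd.DataFrame(
            {"meta_p": [0.05 / m, 0.04 / m, 0.06 / m]},
            index=["at", "below", "above"],
        )
        assert call_dmps(meta, m=m) == ["below"]

    def test_family_wise_error_controlled_under_null(self, rng):
        """Bonferroni on meta p-values keeps FWER near alpha under the null."""
        hits = 0
        reps = 200
        for _ in range(reps):
            eff = pd.DataFrame(rng.normal(0, 0.1, size=(100, 3)))
            se = pd.DataFrame(np.full((100, 3), 0.1))
            meta = ivw_meta(eff, se, method="fixed")
            hits += len(call_dmps(meta)) > 0
        # binomial 99% upper bound around alpha=0.05
        assert hits / reps < 0.05 + 2.6 * np.sqrt(0.05 * 0.95 / reps)
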