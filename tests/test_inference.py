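"""Mixed-model engine: REML estimates, Satterthwaite dfs, AMEs, power."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import mapseg as ms
from mapseg.inference import _design_matrix, build_power_design

FIXED_FACTORIAL = ((), ("trend",), ("invasive",), ("saturation",),
                   ("trend", "invasive"), ("trend", "saturation"),
                   ("invasive", "saturation"),
                   ("trend", "invasive", "saturation"))


def simulate_factorial(n_participants, beta, seed, experiment=2,
                       vc=ms.TABLE6_COMPONENTS):
    """Agreement table drawn from the mixed-model data-generating process."""
    rng = np.random.default_rng(seed)
    base = build_power_design(experiment)
    X = _design_matrix(base, FIXED_FACTORIAL)
    Z = X[:, :4]
    G = vc.covariance()
    b = rng.standard_normal((n_participants, 4)) @ np.linalg.cholesky(
        G + 1e-12 * np.eye(4)).T
    eps = rng.normal(0, np.sqrt(vc.residual), (n_participants, len(base)))
    y = (X @ np.asarray(beta))[None, :] + b @ Z.T + eps
    tab = pd.concat([base] * n_participants, ignore_index=True)
    tab["participant_id"] = np.repeat(np.arange(n_participants), len(base))
    tab["agreement"] = y.ravel()
    tab["framing"] = np.where(tab.invasive == 1, "invasive", "endangered")
    tab["salience_factor"] = np.where(tab.saturation == 1, "saturation", "hue")
    return tab


BETA_TRUE = np.array([0.57, -0.002, 0.008, 0.022, 0.005, -0.029, 0.003, 0.046])


@pytest.fixture(scope="module")
def factorial_fit():
    tab = simulate_factorial(40, BETA_TRUE, seed=42)
    return tab, ms.fit_factorial(tab)


class TestFitLMM:
    def test_intercept_only_recovers_grand_mean(self):
        tab = simulate_factorial(12, BETA_TRUE, seed=1)
        spec = ms.LMMSpec(outcome="agreement", fixed=((),),
                          random=ms.RandomSlopes("participant_id"),
                          df_method="residual")
        res = ms.fit_lmm(tab, spec)
        assert res.coef("Intercept") == pytest.approx(tab.agreement.mean(),
                                                      abs=1e-9)

    def test_rank_deficiency_names_aliased_terms(self):
        tab = simulate_factorial(6, BETA_TRUE, seed=2)
        tab["dup"] = tab["trend"]
        spec = ms.LMMSpec(outcome="agreement",
                          fixed=((), ("trend",), ("dup",)),
                          random=ms.RandomSlopes("participant_id"))
        with pytest.raises(ValueError, match="dup|trend"):
            ms.fit_lmm(tab, spec)

    def test_constant_outcome_gives_zero_slopes(self):
        tab = simulate_factorial(6, BETA_TRUE, seed=3)
        tab["agreement"] = 0.5
        tab["participant_id"] = tab["participant_id"].astype(str)
        tab["stimulus_id"] = tab["stimulus_id"].astype(str)
        rng = np.random.default_rng(0)
        stim = sorted(tab.stimulus_id.unique())
        sv = dict(zip(stim, rng.uniform(10, 20, len(stim))))
        mslope = dict(zip(stim, rng.uniform(0.01, 0.2, len(stim))))
        tab["summed_values"] = tab.stimulus_id.map(sv)
        tab["max_slope"] = tab.stimulus_id.map(mslope)
        res = ms.exploratory_descriptor_model(tab)
        est = res.coefficients["estimate"]
        assert est["Intercept"] == pytest.approx(0.5)
        assert (est.drop("Intercept") == 0).all()

    def test_boundary_variances_reported_not_hidden(self):
        # data with no participant effects at all: variances land at ~0
        tab = simulate_factorial(25, BETA_TRUE, seed=4,
                                 vc=ms.VarianceComponents(
                                     variances=(1e-12,) * 4,
                                     corr=tuple(tuple(np.eye(4)[i])
                                                for i in range(4)),
                                     residual=0.03))
        res = ms.fit_factorial(tab, df_method="residual")
        assert all(v >= 0 for v in res.re_variances.values())
        assert res.sigma2 == pytest.approx(0.03, rel=0.2)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R toolchain not on PATH")
class TestAgainstLme4:
    """Independent oracle: the same models fit with lme4 + lmerTest."""

    def _run_r(self, script, tmp_path):
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, cwd=tmp_path, timeout=300)
        assert out.returncode == 0, out.stderr
        return json.loads(out.stdout)

    def test_random_slopes_model_matches(self, tmp_path, factorial_fit):
        tab, res = factorial_fit
        csv = tmp_path / "d.csv"
        tab.to_csv(csv, index=False)
        script = f"""
suppressMessages({{library(lme4); library(lmerTest); library(jsonlite)}})
d <- read.csv("{csv}")
m <- lmer(agreement ~ trend*invasive*saturation +
          (trend+invasive+saturation | participant_id), data=d, REML=TRUE,
          control=lmerControl(optimizer="bobyqa"))
s <- summary(m)$coefficients
cat(toJSON(list(beta=s[,1], se=s[,2], df=s[,3], p=s[,5],
                sigma2=sigma(m)^2,
                revar=as.numeric(diag(VarCorr(m)$participant_id))),
           digits=10))
"""
        ref = self._run_r(script, tmp_path)
        co = res.coefficients
        assert np.allclose(co["estimate"], ref["beta"], atol=1e-5)
        assert np.allclose(co["se"], ref["se"], rtol=1e-3)
        assert np.allclose(co["df"], ref["df"], rtol=0.02)
        assert np.allclose(co["p"], ref["p"], rtol=0.05, atol=1e-6)
        assert res.sigma2 == pytest.approx(ref["sigma2"][0], rel=1e-4)
        assert np.allclose(list(res.re_variances.values()), ref["revar"],
                           atol=2e-5)

    def test_crossed_intercepts_model_matches(self, tmp_path):
        tab = simulate_factorial(15, BETA_TRUE, seed=7)
        rng = np.random.default_rng(3)
        stim_fx = dict(zip(sorted(tab.stimulus_id.unique()),
                           rng.normal(0, 0.05, tab.stimulus_id.nunique())))
        tab["agreement"] += tab.stimulus_id.map(stim_fx)
        csv = tmp_path / "d.csv"
        tab.to_csv(csv, index=False)
        spec = ms.LMMSpec(outcome="agreement", fixed=((), ("trend",)),
                          random=ms.CrossedIntercepts(("participant_id",
                                                       "stimulus_id")))
        res = ms.fit_lmm(tab, spec)
        script = f"""
suppressMessages({{library(lme4); library(lmerTest); library(jsonlite)}})
d <- read.csv("{csv}")
m <- lmer(agreement ~ trend + (1 | participant_id) + (1 | stimulus_id),
          data=d, REML=TRUE)
s <- summary(m)$coefficients
v <- as.data.frame(VarCorr(m))
cat(toJSON(list(beta=s[,1], se=s[,2], df=s[,3], sigma2=sigma(m)^2,
                revar=v$vcov[1:2], grp=v$grp[1:2]), digits=10))
"""
        ref = self._run_r(script, tmp_path)
        co = res.coefficients
        assert np.allclose(co["estimate"], ref["beta"], atol=1e-6)
        assert np.allclose(co["se"], ref["se"], rtol=1e-3)
        assert np.allclose(co["df"], ref["df"], rtol=0.02)
        got = {k.split(":")[0]: v for k, v in res.re_variances.items()}
        want = dict(zip(ref["grp"], ref["revar"]))
        for grp, v in want.items():
            assert got[grp] == pytest.approx(v, abs=1e-6)


class TestAME:
    def test_reference_cell_equals_trend_coefficient(self, factorial_fit):
        _, res = factorial_fit
        a = ms.ame_trend(res, "endangered", "hue")
        assert a.ame == pytest.approx(res.coef("trend"), abs=1e-12)
        assert a.se == pytest.approx(res.coefficients.loc["trend", "se"],
                                     abs=1e-12)

    def test_coefficient_sum_equals_numeric_derivative(self, factorial_fit):
        tab, res = factorial_fit
        for framing in ("endangered", "invasive"):
            for sal in ("hue", "saturation"):
                a = ms.ame_trend(res, framing, sal)
                num = ms.ame_trend_numeric(res, tab, framing, sal)
                assert a.ame == pytest.approx(num, abs=1e-8)

    def test_cell_sum_identity(self, factorial_fit):
        _, res = factorial_fit
        total = sum(ms.ame_trend(res, f, s).ame
                    for f in ("endangered", "invasive")
                    for s in ("hue", "saturation"))
        c = res.coefficients["estimate"]
        expected = (4 * c["trend"] + 2 * c["trend:invasive"]
                    + 2 * c["trend:saturation"]
                    + c["trend:invasive:saturation"])
        assert total == pytest.approx(expected, abs=1e-12)

    def test_missing_interaction_rejected(self):
        tab = simulate_factorial(10, BETA_TRUE, seed=5)
        tab = ms.encode_treatment(tab, "framing", "endangered")
        spec = ms.LMMSpec(outcome="agreement", fixed=((), ("trend",)),
                          random=ms.RandomSlopes("participant_id"),
                          df_method="residual")
        res = ms.fit_lmm(tab, spec)
        res.factor_meta = {"salience_positive": "saturation",
                           "salience_reference": "hue"}
        with pytest.raises(ValueError, match="missing interaction"):
            ms.ame_trend(res, "invasive", "saturation")


class TestCoverageAndCalibration:
    def test_wald_ci_coverage(self):
        # 95% CIs for the three-way coefficient on data simulated from the
        # fitted spec should cover the truth ~95% of the time
        hits = 0
        reps = 300
        for rep in range(reps):
            tab = simulate_factorial(30, BETA_TRUE, seed=10_000 + rep)
            res = ms.fit_factorial(tab, df_method="residual")
            row = res.coefficients.loc["trend:invasive:saturation"]
            hits += row.ci_low <= BETA_TRUE[-1] <= row.ci_high
        assert 0.93 * reps <= hits + 3 <= 0.97 * reps + 6  # 93-97% band

    def test_permuted_outcome_destroys_interaction(self):
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 120
        for rep in range(reps):
            tab = simulate_factorial(20, BETA_TRUE, seed=20_000 + rep)
            tab["agreement"] = rng.permutation(tab["agreement"].to_numpy())
            res = ms.fit_factorial(tab, df_method="residual")
            rejections += res.coefficients.loc["trend:invasive:saturation",
                                               "p"] < 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rejections / reps - 0.05) < 3 * se + 1e-9


class TestDescriptorModel:
    def _table(self, slope, seed=0, n_part=25, n_stim=15):
        rng = np.random.default_rng(seed)
        trend = rng.uniform(-1, 1, n_stim)
        summed = rng.uniform(20, 40, n_stim)
        mslope = rng.uniform(0.01, 0.3, n_stim)
        rows = []
        for p in range(n_part):
            pe = rng.normal(0, 0.05)
            for s in range(n_stim):
                rows.append({
                    "participant_id": f"p{p}", "stimulus_id": f"s{s}",
                    "trend": trend[s], "summed_values": summed[s],
                    "max_slope": mslope[s],
                    "agreement": 0.5 + slope * trend[s] + pe
                    + rng.normal(0, 0.05)})
        return pd.DataFrame(rows)

    def test_planted_trend_effect_recovered(self):
        res = ms.exploratory_descriptor_model(self._table(0.08, seed=1))
        co = res.coefficients
        assert co.loc["trend", "estimate"] == pytest.approx(0.08, abs=0.02)
        assert co.loc["trend", "p"] < 0.01
        assert co.loc["max_slope", "p"] > 0.05

    def test_permuted_descriptors_give_null_effects(self):
        tab = self._table(0.08, seed=2)
        rng = np.random.default_rng(5)
        stim = sorted(tab.stimulus_id.unique())
        perm = dict(zip(stim, rng.permutation(stim)))
        for col in ("trend", "summed_values", "max_slope"):
            lookup = tab.drop_duplicates("stimulus_id").set_index(
                "stimulus_id")[col]
            tab[col] = tab.stimulus_id.map(perm).map(lookup)
        res = ms.exploratory_descriptor_model(tab)
        assert (res.coefficients.drop("Intercept")["p"] > 0.05).all()


class TestPowerSimulation:
    def test_monotone_in_effect(self):
        powers = [ms.power_simulation(e, 60, experiment=3, reps=80,
                                      seed=9).power
                  for e in (0.0, 0.02, 0.05)]
        assert powers[0] <= powers[1] <= powers[2]

    def test_type_one_error_calibrated(self):
        res = ms.power_simulation(0.0, 60, experiment=3, reps=200, seed=11)
        se = np.sqrt(0.05 * 0.95 / res.reps)
        assert abs(res.power - 0.05) <= 2 * se
        assert res.ci_low <= 0.05 <= res.ci_high

    def test_few_reps_warns(self):
        with pytest.warns(UserWarning):
            ms.power_simulation(0.0, 10, experiment=2, reps=10, seed=0)
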