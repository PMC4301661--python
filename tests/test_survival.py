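"""Cox model: brute-force likelihood oracle, lifelines cross-check,
left-truncation semantics, strata behavior, cause-specific censoring and
the scale-equivariance property that justifies SD-standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from hetsurv import survival as sv
from hetsurv import synthetic_data as sd
from tests.conftest import simulate_simple_survival


def random_small_instance(rng, n=8, truncated=True):
    """Tiny survival dataset with a single binary covariate and at least
    one event in each covariate group (avoids separation)."""
    while True:
        x = rng.integers(0, 2, n).astype(float)
        entry = rng.uniform(0, 2, n) if truncated else np.zeros(n)
        exit_ = entry + rng.uniform(0.5, 10, n)
        event = rng.integers(0, 2, n)
        if event.sum() >= 2 and len(set(x[event == 1])) == 2:
            return pd.DataFrame({"entry_age": entry, "exit_age": exit_,
                                 "dead": event, "x": x})


def brute_force_beta(df, strata_ids=None):
    """Maximize the hand-written partial likelihood on a single covariate."""
    args = (df["entry_age"].to_numpy(), df["exit_age"].to_numpy(),
            df["dead"].to_numpy(), df[["x"]].to_numpy())
    res = optimize.minimize_scalar(
        lambda b: -sv.partial_log_likelihood(np.array([b]), *args,
                                             strata_ids=strata_ids),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10})
    return res.x


def identified_instance(rng, n=8, truncated=True, ties=False):
    """Instance whose partial likelihood has an interior maximum (the
    brute-force optimum screens out monotone-likelihood draws)."""
    while True:
        df = random_small_instance(rng, n=n, truncated=truncated)
        if ties:
            df = df.assign(exit_age=np.round(df["exit_age"]))
            df = df[df["exit_age"] > df["entry_age"]].reset_index(drop=True)
            if df["dead"].sum() < 2 or df["x"][df["dead"] == 1].nunique() < 2:
                continue
        b = brute_force_beta(df)
        if abs(b) < 5:
            return df, b


class TestOracleAgreement:
    @pytest.mark.parametrize("truncated", [False, True])
    def test_matches_brute_force(self, truncated):
        rng = np.random.default_rng(100 + truncated)
        for _ in range(10):
            df, b_ref = identified_instance(rng, n=8, truncated=truncated)
            fit = sv.cox_fit(df, ["x"])
            assert fit.beta["x"] == pytest.approx(b_ref, abs=1e-6)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(200)
        for _ in range(5):
            df, b_ref = identified_instance(rng, n=10, ties=True)
            fit = sv.cox_fit(df, ["x"])
            assert fit.beta["x"] == pytest.approx(b_ref, abs=1e-6)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(4)
        df = simulate_simple_survival(rng, 400, 0.3)
        df["g"] = rng.choice(list("ab"), 400)
        fit = sv.cox_fit(df, ["x"], ["g"])
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="exit_age", event_col="dead",
                entry_col="entry_age", strata=["g"],
                fit_options={"precision": 1e-9})
        assert fit.beta["x"] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se["x"] == pytest.approx(cph.standard_errors_["x"],
                                            rel=1e-5)


class TestModelProperties:
    def test_score_at_optimum_below_tolerance(self):
        rng = np.random.default_rng(9)
        df = simulate_simple_survival(rng, 300, 0.4)
        fit = sv.cox_fit(df, ["x"])
        args = (df["entry_age"].to_numpy(), df["exit_age"].to_numpy(),
                df["dead"].to_numpy(), df[["x"]].to_numpy())
        eps = 1e-6
        b = fit.beta["x"]
        score = (sv.partial_log_likelihood(np.array([b + eps]), *args)
                 - sv.partial_log_likelihood(np.array([b - eps]), *args)) / (2 * eps)
        assert abs(score) < 1e-4  # numeric-diff resolution of the oracle

    def test_no_events_rejected(self):
        df = pd.DataFrame({"entry_age": [1.0, 2.0], "exit_age": [5.0, 6.0],
                           "dead": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(sv.CoxFitError, match="no events"):
            sv.cox_fit(df, ["x"])

    def test_record_duplication_halves_information(self):
        rng = np.random.default_rng(13)
        df = simulate_simple_survival(rng, 150, 0.5)
        fit1 = sv.cox_fit(df, ["x"])
        fit2 = sv.cox_fit(pd.concat([df, df], ignore_index=True), ["x"])
        # Efron's tie correction shifts beta only marginally
        assert fit2.beta["x"] == pytest.approx(fit1.beta["x"], rel=0.02)
        assert fit2.se["x"] * np.sqrt(2) == pytest.approx(fit1.se["x"],
                                                          rel=0.02)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(14)
        df = simulate_simple_survival(rng, 250, -0.3)
        df["bmi"] = rng.normal(27, 4, 250)
        c = 5.3
        fit1 = sv.cox_fit(df, ["x", "bmi"])
        fit2 = sv.cox_fit(df.assign(x=df["x"] * c), ["x", "bmi"])
        assert abs(fit2.beta["x"] * c - fit1.beta["x"]) < 1e-10
        assert abs(fit2.z["x"] - fit1.z["x"]) < 1e-10
        assert abs(fit2.beta["x"] * (df["x"] * c).std(ddof=1)
                   - fit1.beta["x"] * df["x"].std(ddof=1)) < 1e-10

    def test_left_truncation_ignores_pre_event_exits(self):
        rng = np.random.default_rng(15)
        df = simulate_simple_survival(rng, 100, 0.4, entry_range=(50.0, 60.0))
        fit1 = sv.cox_fit(df, ["x"])
        extra = pd.DataFrame({"entry_age": [10.0], "exit_age": [20.0],
                              "dead": [0], "x": [3.0]})
        fit2 = sv.cox_fit(pd.concat([df, extra], ignore_index=True), ["x"])
        assert fit2.beta["x"] == pytest.approx(fit1.beta["x"], abs=1e-12)
        assert fit2.se["x"] == pytest.approx(fit1.se["x"], abs=1e-12)

    def test_consistency_scaled(self):
        # planted beta recovered on average over replicates
        beta = np.log(0.8)
        rng = np.random.default_rng(16)
        est = []
        for _ in range(20):
            df = simulate_simple_survival(rng, 2000, beta, censor_age=1e9)
            est.append(sv.cox_fit(df, ["x"]).beta["x"])
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - beta) < 2 * mc_se


class TestStrata:
    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(17)
        df = simulate_simple_survival(rng, 200, 0.3)
        df["g"] = "only"
        fit_a = sv.cox_fit(df, ["x"])
        fit_b = sv.cox_fit(df, ["x"], ["g"])
        assert fit_a.beta["x"] == pytest.approx(fit_b.beta["x"], abs=1e-10)

    def test_two_identical_strata_keep_beta(self):
        rng = np.random.default_rng(18)
        df = simulate_simple_survival(rng, 150, 0.4)
        dup = pd.concat([df.assign(g="a"), df.assign(g="b")],
                        ignore_index=True)
        fit_one = sv.cox_fit(df, ["x"])
        fit_two = sv.cox_fit(dup, ["x"], ["g"])
        assert fit_two.beta["x"] == pytest.approx(fit_one.beta["x"],
                                                  abs=1e-8)
        assert fit_two.se["x"] == pytest.approx(fit_one.se["x"] / np.sqrt(2),
                                                rel=1e-6)

    def test_missing_education_is_a_level(self):
        rng = np.random.default_rng(19)
        df = simulate_simple_survival(rng, 120, 0.0)
        df["education"] = rng.choice(["1", "2", "Missing"], 120)
        design = sv.stratified_design(df, ["education"])
        assert "Missing" in set(design["education"])
        fit = sv.cox_fit(df, ["x"], ["education"])
        assert np.isfinite(fit.beta["x"])

    def test_eventless_stratum_contributes_nothing(self):
        rng = np.random.default_rng(20)
        df = simulate_simple_survival(rng, 100, 0.3)
        df["g"] = "a"
        alive = pd.DataFrame({"entry_age": [50.0] * 5, "exit_age": [60.0] * 5,
                              "dead": [0] * 5, "x": rng.normal(size=5),
                              "g": ["b"] * 5})
        fit1 = sv.cox_fit(df, ["x"], ["g"])
        fit2 = sv.cox_fit(pd.concat([df, alive], ignore_index=True),
                          ["x"], ["g"])
        assert fit1.beta["x"] == pytest.approx(fit2.beta["x"], abs=1e-12)


class TestCauseSpecific:
    def make_causes(self, rng, n=800):
        z = rng.standard_normal(n)
        entry = rng.uniform(50, 70, n)
        out = sd.simulate_survival(z, np.zeros(n), np.log(0.8), 0.03,
                                   entry, 95.0, rng)
        return out.assign(x=z)

    def test_single_cause_dataset_equals_all_cause(self):
        rng = np.random.default_rng(23)
        df = self.make_causes(rng)
        df.loc[df["dead"] == 1, "cause"] = "cancer"
        fit_all = sv.cox_fit(df, ["x"])
        fit_cancer = sv.cause_specific_fit(df, "cancer", ["x"])
        assert fit_cancer.beta["x"] == pytest.approx(fit_all.beta["x"],
                                                     abs=1e-12)

    def test_event_partition(self):
        rng = np.random.default_rng(24)
        df = self.make_causes(rng)
        total = sum(sv.cause_specific_fit(df, c, ["x"]).n_events
                    for c in ("cancer", "cvd", "other"))
        assert total == int(df["dead"].sum())

    def test_absent_cause_rejected(self):
        rng = np.random.default_rng(25)
        df = self.make_causes(rng)
        df.loc[df["cause"] == "cvd", "cause"] = "cancer"
        with pytest.raises(sv.CoxFitError):
            sv.cause_specific_fit(df, "cvd", ["x"])

    def test_planted_cause_effect_recovered(self):
        rng = np.random.default_rng(26)
        n = 6000
        z = rng.standard_normal(n)
        entry = rng.uniform(50, 70, n)
        extra = np.log(0.6)
        out = sd.simulate_survival(
            z, np.zeros(n), 0.0, 0.03, entry, 95.0, rng,
            cause_log_hr={"cancer": extra})
        df = out.assign(x=z)
        fit = sv.cause_specific_fit(df, "cancer", ["x"])
        assert abs(fit.beta["x"] - extra) < 2 * fit.se["x"]
        fit_other = sv.cause_specific_fit(df, "other", ["x"])
        assert abs(fit_other.beta["x"]) < 3 * fit_other.se["x"]
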