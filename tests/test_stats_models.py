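"""Model fits, AICc ranking, repeatability, marginal means, correlation."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from usvkit.stats_models import (
    _point_R,
    aicc,
    aicc_rank,
    contact_rate_model,
    fit_asymmetry_lm,
    fit_lmm,
    fit_pinning_glm,
    fit_usv22_glmm,
    fit_usv_lmm,
    marginal_means,
    repeatability,
    spearman,
)
from usvkit.synthetic import CohortDesign, GenerativeParams, simulate_play_bouts, simulate_usv_counts


@pytest.fixture(scope="module")
def cohort():
    design = CohortDesign(seed=3)
    params = GenerativeParams()
    return dict(
        design=design,
        params=params,
        sessions=simulate_usv_counts(design, params, seed=10),
        play=simulate_play_bouts(design, params, seed=11),
    )


class TestPinningGlm:
    def test_constant_counts_give_log_intercept(self):
        df = pd.DataFrame(
            dict(
                treatment=["control", "social_reduced"] * 10,
                batch=["A", "C"] * 10,
                pinnings_received=[7] * 20,
                pinnings_delivered=[7] * 20,
            )
        )
        fit = fit_pinning_glm(df)
        assert fit.params["Intercept"] == pytest.approx(np.log(7), abs=1e-6)
        assert np.allclose(fit.params.iloc[1:], 0.0, atol=1e-6)

    def test_parameter_recovery_large_n(self):
        """1000+ rats recover (3.20, -0.45, -0.82) within +-0.05."""
        design = CohortDesign(
            batch_sizes=(("A", 600), ("C", 600)),
            days_per_batch=(("A", 1), ("C", 1)),
            seed=4,
        )
        fit = fit_pinning_glm(simulate_play_bouts(design, seed=12))
        assert fit.params["Intercept"] == pytest.approx(3.20, abs=0.05)
        assert fit.params[
            "C(treatment, Treatment('control'))[T.social_reduced]"
        ] == pytest.approx(-0.45, abs=0.05)
        assert fit.params["C(batch)[T.C]"] == pytest.approx(-0.82, abs=0.05)

    def test_kinematic_group_excluded(self, cohort):
        fit = fit_pinning_glm(cohort["play"])
        assert fit.n == (cohort["play"].treatment != "kinematic_reduced").sum()


class TestAsymmetryLm:
    def test_constant_response(self):
        df = pd.DataFrame(
            dict(
                treatment=["control", "social_reduced"] * 10,
                batch=["A", "C"] * 10,
                asymmetry=[0.25] * 20,
                pinnings_delivered=[5] * 20,
                pinnings_received=[3] * 20,
            )
        )
        fit = fit_asymmetry_lm(df)
        assert fit.params["Intercept"] == pytest.approx(0.25, abs=1e-10)
        assert np.allclose(fit.params.iloc[1:], 0.0, atol=1e-10)

    def test_computes_score_when_missing(self, cohort):
        fit = fit_asymmetry_lm(cohort["play"])
        assert "asymmetry" in fit.data.columns
        assert fit.data.asymmetry.between(-1, 1).all()


class TestGaussianLmm:
    def test_zero_rat_variance_detected(self):
        params = GenerativeParams(sd_rat=0.0, sd_litter=0.0, sd_resid=5.0)
        sess = simulate_usv_counts(CohortDesign(seed=1), params, seed=13, floor_at_zero=False)
        fit = fit_usv_lmm(sess)
        assert fit.vc["rat"] / fit.vc["residual"] < 0.05

    def test_day_slope_recovered_on_average(self):
        ests = []
        for s in range(8):
            sess = simulate_usv_counts(CohortDesign(seed=2), seed=200 + s)
            ests.append(fit_usv_lmm(sess).params["day"])
        assert np.mean(ests) == pytest.approx(3.09, abs=0.8)

    def test_missing_random_term_is_hard_error(self, cohort):
        broken = cohort["sessions"].drop(columns=["litter_id"])
        with pytest.raises(Exception):
            fit_usv_lmm(broken)

    def test_agrees_with_lme4(self, cohort, tmp_path):
        """Independent oracle: lme4::lmer on the same data (ML fit)."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the lme4 cross-check")
        sess = cohort["sessions"]
        csv = tmp_path / "sess.csv"
        sess.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(n50 ~ day + order + (1|litter_id) + (1|rat_id), data=d, REML=FALSE)
            vc <- as.data.frame(VarCorr(m))
            cat(fixef(m)["day"], fixef(m)["order"], logLik(m),
                vc$vcov[vc$grp=="rat_id"], vc$vcov[vc$grp=="litter_id"],
                vc$vcov[vc$grp=="Residual"], sep=",")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        day_r, order_r, llf_r, vr_r, vl_r, ve_r = map(float, out.stdout.strip().split(","))
        fit = fit_lmm(sess, "n50 ~ day + order", reml=False)
        assert fit.params["day"] == pytest.approx(day_r, rel=1e-4)
        assert fit.params["order"] == pytest.approx(order_r, rel=1e-4)
        assert fit.llf == pytest.approx(llf_r, abs=0.05)
        assert fit.vc["rat"] == pytest.approx(vr_r, rel=0.02)
        assert fit.vc["residual"] == pytest.approx(ve_r, rel=0.02)


class TestPoissonGlmm:
    def test_agrees_with_glmer(self, cohort, tmp_path):
        """Independent oracle: lme4::glmer (Laplace) on the same data."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the glmer cross-check")
        sess = cohort["sessions"]
        csv = tmp_path / "sess.csv"
        sess.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(n22 ~ batch + day + (1|rat_id) + (1|litter_id),
                       data=d, family=poisson)
            vc <- as.data.frame(VarCorr(m))
            cat(fixef(m)["(Intercept)"], fixef(m)["day"], logLik(m),
                vc$vcov[vc$grp=="rat_id"], sep=",")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        int_r, day_r, llf_r, vr_r = map(float, out.stdout.strip().split(","))
        fit = fit_usv22_glmm(sess, "n22 ~ C(batch) + day")
        assert fit.params["Intercept"] == pytest.approx(int_r, abs=0.02)
        assert fit.params["day"] == pytest.approx(day_r, abs=0.005)
        assert fit.llf == pytest.approx(llf_r, abs=1.0)
        assert fit.vc["rat"] == pytest.approx(vr_r, rel=0.10)

    def test_recovers_generating_coefficients(self, cohort):
        fit = fit_usv22_glmm(cohort["sessions"], "n22 ~ C(batch) + day")
        assert fit.params["day"] == pytest.approx(0.17, abs=0.05)
        assert fit.params["C(batch)[T.B]"] == pytest.approx(2.13, abs=0.5)


class TestAicc:
    def test_identity_against_aic(self, cohort):
        fit = fit_usv_lmm(cohort["sessions"], reml=False)
        k, n = fit.k, fit.n
        aic = -2 * fit.llf + 2 * k
        assert aicc(fit) - aic == pytest.approx(2 * k * (k + 1) / (n - k - 1))

    def test_single_candidate_is_best(self, cohort):
        fit = fit_usv_lmm(cohort["sessions"], reml=False)
        comp = aicc_rank([fit])
        assert comp.delta_aicc == [0.0]

    def test_undefined_for_tiny_n(self, cohort):
        fit = fit_usv_lmm(cohort["sessions"], reml=False)
        fit.n = fit.k + 1
        with pytest.raises(ValueError, match="undefined"):
            aicc(fit)

    def test_true_day_effect_preferred(self):
        """Dropping a real day effect loses the AICc ranking (most seeds)."""
        wins = 0
        n_seeds = 12
        for s in range(n_seeds):
            sess = simulate_usv_counts(CohortDesign(seed=5), seed=300 + s)
            with_day = fit_lmm(sess, "n50 ~ day + order", reml=False, label="with")
            without = fit_lmm(sess, "n50 ~ order", reml=False, label="without")
            wins += aicc_rank([with_day, without]).best == "with"
        assert wins >= int(0.9 * n_seeds)

    def test_different_data_rejected(self, cohort):
        f1 = fit_usv_lmm(cohort["sessions"], reml=False)
        f2 = fit_usv_lmm(cohort["sessions"].iloc[:-10], reml=False)
        with pytest.raises(ValueError, match="identical data"):
            aicc_rank([f1, f2])


class TestRepeatability:
    def test_closed_form_half(self):
        params = GenerativeParams(sd_rat=30.0, sd_litter=0.0, sd_resid=30.0)
        sess = simulate_usv_counts(CohortDesign(seed=6), params, seed=14, floor_at_zero=False)
        fit = fit_usv_lmm(sess)
        rep = repeatability(fit, "rat", n_boot=0)
        assert rep.R == pytest.approx(0.5, abs=0.1)

    def test_shift_invariance_gaussian(self, cohort):
        fit = fit_usv_lmm(cohort["sessions"])
        shifted = cohort["sessions"].copy()
        shifted["n50"] = shifted["n50"] + 1000
        fit2 = fit_usv_lmm(shifted)
        r1 = repeatability(fit, "rat", n_boot=0).R
        r2 = repeatability(fit2, "rat", n_boot=0).R
        assert r1 == pytest.approx(r2, abs=1e-6)
        assert 0.0 <= r1 <= 1.0

    def test_bootstrap_ci_brackets_point_estimate(self, cohort):
        fit = fit_usv_lmm(cohort["sessions"])
        rep = repeatability(fit, "rat", n_boot=40, seed=7)
        assert rep.n_boot >= 35
        assert rep.ci_lo <= rep.R <= rep.ci_hi
        assert 0.0 <= rep.ci_lo <= rep.ci_hi <= 1.0

    def test_unknown_term_rejected(self, cohort):
        fit = fit_usv_lmm(cohort["sessions"])
        with pytest.raises(ValueError):
            repeatability(fit, "cage", n_boot=0)


class TestMarginalMeans:
    def test_balanced_one_factor_equals_cell_means(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            dict(
                treatment=np.repeat(["control", "social_reduced"], 40),
                batch=np.tile(["A", "C"], 40),
                pinnings_delivered=rng.poisson(12, 80),
                pinnings_received=rng.poisson(10, 80),
            )
        )
        df["asymmetry"] = (df.pinnings_delivered - df.pinnings_received) / (
            df.pinnings_delivered + df.pinnings_received
        )
        fit = fit_asymmetry_lm(df)
        mm = marginal_means(fit, "treatment")
        cell = df.groupby("treatment").asymmetry.mean()
        for _, row in mm.means.iterrows():
            assert row["mean"] == pytest.approx(cell[row["level"]], abs=1e-9)

    def test_poisson_response_scale(self, cohort):
        fit = fit_pinning_glm(cohort["play"])
        mm = marginal_means(fit, "treatment")
        ctl = mm.means.set_index("level").loc["control"]
        # equal-weight link average: exp(b0 + bC/2)
        expected = np.exp(
            fit.params["Intercept"] + 0.5 * fit.params["C(batch)[T.C]"]
        )
        assert ctl["mean"] == pytest.approx(expected, rel=1e-9)
        assert ctl["ci_lo"] < ctl["mean"] < ctl["ci_hi"]
        assert len(mm.contrasts) == 1
        assert 0 <= mm.contrasts.p_tukey.iloc[0] <= 1

    def test_unknown_factor_rejected(self, cohort):
        fit = fit_pinning_glm(cohort["play"])
        with pytest.raises(ValueError):
            marginal_means(fit, "cage")


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman(x, x**3)[0] == pytest.approx(1.0)
        assert spearman(x, -np.exp(x))[0] == pytest.approx(-1.0)

    def test_five_point_example_matches_rank_oracle(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 0.5, 9.0, 7.0, 3.0]

        def ranks(v):
            order = np.argsort(v)
            r = np.empty(len(v))
            r[order] = np.arange(1, len(v) + 1)
            return r

        rx, ry = ranks(x), ranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestContactRateModel:
    @staticmethod
    def _rates_df(ventral_boost, dorsal_boost, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for b in "AB":
            for r in range(6):
                rat = f"{b}R{r}"
                lit = f"{b}L{r % 2}"
                for day in (1, 2, 3):
                    base = 0.8 + rng.normal(0, 0.1)
                    for pt, boost in (
                        ("none", 0.0),
                        ("ventral", ventral_boost),
                        ("dorsal", dorsal_boost),
                    ):
                        rows.append(
                            dict(
                                rat_id=rat, litter_id=lit, treatment="control",
                                batch=b, day=day, period_type=pt,
                                total_duration_s=30.0,
                                rate_per_s=base + boost + rng.normal(0, 0.05),
                            )
                        )
        return pd.DataFrame(rows)

    def test_no_period_effect_when_rates_equal(self):
        df = self._rates_df(0.0, 0.0, seed=9)
        fit = contact_rate_model(df, "rate_per_s ~ C(period_type, Treatment('none'))")
        assert np.allclose(fit.params.iloc[1:], 0.0, atol=0.05)

    def test_recovers_contact_boosts(self):
        df = self._rates_df(1.2, 1.2, seed=10)
        fit = contact_rate_model(df, "rate_per_s ~ C(period_type, Treatment('none'))")
        v = fit.params["C(period_type, Treatment('none'))[T.ventral]"]
        d = fit.params["C(period_type, Treatment('none'))[T.dorsal]"]
        assert v == pytest.approx(1.2, abs=0.05)
        assert d == pytest.approx(1.2, abs=0.05)
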