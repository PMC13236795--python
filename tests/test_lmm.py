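"""Crossed mixed model: REML estimates, Satterthwaite df, EMMs, Tukey.

Oracles: ordinary least squares (degenerate random effects), dense-matrix
GLS at known variance components, statsmodels MixedLM (variance-components
parameterization of the crossed design), and R lme4/lmerTest/emmeans run
through Rscript on one frozen dataset.
"""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from stepinit.lmm import CrossedLMM, semipartial_r2
from stepinit.power import simulation_design, simulate_response

EMOTIONS = ("angry", "fearful", "happy")
CONDITIONS = ("face_gender", "neutral_vs_emotional")


@pytest.fixture(scope="module")
def small_data():
    design = simulation_design(12, 6, 2)
    rng = np.random.default_rng(42)
    y = simulate_response(design, rng, None, sd_participant=1.0, sd_face=0.4, sd_residual=1.0)
    return design.assign(value=y)


@pytest.fixture(scope="module")
def small_fit(small_data):
    return CrossedLMM.from_dataframe(small_data, value_col="value").fit()


class TestSemipartialR2:
    def test_formula_values(self):
        assert semipartial_r2(0.0, 1, 90) == 0.0
        assert semipartial_r2(10.0, 1, 90) == pytest.approx((10 / 90) / (1 + 10 / 90))
        assert semipartial_r2(1e9, 1, 90) == pytest.approx(1.0, abs=1e-6)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            semipartial_r2(1.0, 0, 10)
        with pytest.raises(ValueError):
            semipartial_r2(-1.0, 1, 10)


class TestDegenerateRandomEffects:
    def test_ols_equivalence(self, small_data):
        model = CrossedLMM.from_dataframe(small_data, value_col="value")
        res = model.fit(vc_fixed={"participant": 0.0, "face": 0.0})
        beta_ols = np.linalg.lstsq(model.X, model.y, rcond=None)[0]
        assert np.max(np.abs(res.params - beta_ols) / np.abs(beta_ols)) < 1e-6

    def test_satterthwaite_df_collapses_to_n_minus_p(self, small_data):
        model = CrossedLMM.from_dataframe(small_data, value_col="value")
        res = model.fit(vc_fixed={"participant": 0.0, "face": 0.0})
        an = res.anova()
        assert (an["df_den"] == model.N - model.p).all()

    def test_constant_outcome_flags_residual_boundary(self, small_data):
        df = small_data.assign(value=3.0)
        res = CrossedLMM.from_dataframe(df, value_col="value").fit(n_restarts=1)
        assert "residual" in res.boundary


class TestComponentRecovery:
    def test_variance_components_recovered(self):
        """sigma_p^2 = 4, sigma_e^2 = 1: mean REML estimates within 10%."""
        design = simulation_design(20, 8, 2)
        model = CrossedLMM.from_dataframe(design.assign(value=0.0), value_col="value")
        rng = np.random.default_rng(1)
        est_p, est_e = [], []
        for _ in range(60):
            y = simulate_response(design, rng, None, sd_participant=2.0, sd_face=0.0, sd_residual=1.0)
            res = model.set_response(y).fit(n_restarts=1, start=(4.0, 0.01))
            est_p.append(res.vcomp["participant"])
            est_e.append(res.vcomp["residual"])
        assert np.mean(est_p) == pytest.approx(4.0, rel=0.10)
        assert np.mean(est_e) == pytest.approx(1.0, rel=0.10)

    def test_reml_criterion_is_a_local_optimum(self, small_data, small_fit):
        """Deviance at the estimate beats 100 perturbed parameter points."""
        model = CrossedLMM.from_dataframe(small_data, value_col="value")
        at_hat = model.reml_deviance(**{
            "sigma2_p": small_fit.vcomp["participant"],
            "sigma2_f": small_fit.vcomp["face"],
            "sigma2_e": small_fit.vcomp["residual"],
        })
        rng = np.random.default_rng(0)
        for _ in range(100):
            f = rng.uniform(0.5, 2.0, 3)
            dev = model.reml_deviance(
                small_fit.vcomp["participant"] * f[0],
                small_fit.vcomp["face"] * f[1],
                small_fit.vcomp["residual"] * f[2],
            )
            assert dev >= at_hat - 1e-6


class TestStatsmodelsOracle:
    def test_vcomp_and_fixed_effects_match(self, small_data):
        smf = pytest.importorskip("statsmodels.formula.api")
        res = CrossedLMM.from_dataframe(small_data, value_col="value").fit()
        md = smf.mixedlm(
            "value ~ C(emotion, Sum)*C(condition, Sum)",
            small_data,
            groups=np.ones(len(small_data)),
            vc_formula={"p": "0 + C(participant_id)", "f": "0 + C(face_id)"},
        )
        mf = md.fit(reml=True)
        assert res.vcomp["residual"] == pytest.approx(mf.scale, rel=1e-3)
        sm_vc = sorted(mf.vcomp)
        ours = sorted([res.vcomp["participant"], res.vcomp["face"]])
        assert ours == pytest.approx(sm_vc, rel=1e-3, abs=1e-4)


class TestEmmeans:
    def test_balanced_emm_equals_cell_means(self):
        design = simulation_design(10, 5, 2)
        rng = np.random.default_rng(3)
        means = {(e, c): 10.0 * i for i, (e, c) in enumerate(
            (e, c) for e in EMOTIONS for c in CONDITIONS)}
        y = simulate_response(design, rng, means, 0.5, 0.2, 0.5)
        df = design.assign(value=y)
        res = CrossedLMM.from_dataframe(df, value_col="value").fit()
        emm = res.emmeans().set_index(["emotion", "condition"])["emmean"]
        cell = df.groupby(["emotion", "condition"])["value"].mean()
        for key in cell.index:
            assert emm[key] == pytest.approx(cell[key], abs=1e-6)

    def test_unbalanced_emm_matches_dense_gls_oracle(self, small_data, small_fit):
        """Drop rows -> EMMs equal a from-scratch dense GLS prediction."""
        df = small_data.iloc[:-17].reset_index(drop=True)
        model = CrossedLMM.from_dataframe(df, value_col="value")
        res = model.fit()
        # dense-matrix GLS at the fitted components (independent route)
        Zp = pd.get_dummies(df["participant_id"]).to_numpy(float)
        Zf = pd.get_dummies(df["face_id"]).to_numpy(float)
        V = (
            res.vcomp["participant"] * Zp @ Zp.T
            + res.vcomp["face"] * Zf @ Zf.T
            + res.vcomp["residual"] * np.eye(len(df))
        )
        Vi = np.linalg.inv(V)
        X = model.X
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ model.y)
        emm = res.emmeans()
        for _, g in model.cell_grid.iterrows():
            pred = float(g["row"] @ beta)
            got = emm[(emm.emotion == g["emotion"]) & (emm.condition == g["condition"])]["emmean"].iloc[0]
            assert got == pytest.approx(pred, abs=1e-8)

    def test_contrast_of_emms_is_emm_difference(self, small_fit):
        emm = small_fit.emmeans().set_index(["emotion", "condition"])["emmean"]
        pw = small_fit.pairwise("emotion", by="condition")
        row = pw[(pw.contrast == "angry - fearful") & (pw.condition == "face_gender")].iloc[0]
        assert row["estimate"] == pytest.approx(
            emm[("angry", "face_gender")] - emm[("fearful", "face_gender")], abs=1e-10
        )


class TestTukey:
    def test_adjusted_p_at_least_unadjusted(self, small_fit):
        pw = small_fit.pairwise("emotion", by="condition")
        assert (pw["p_adjusted"] >= pw["p_unadjusted"] - 1e-12).all()

    def test_family_of_two_equals_t_test(self, small_fit):
        pw = small_fit.pairwise("condition")
        assert len(pw) == 1
        assert pw["p_adjusted"].iloc[0] == pytest.approx(pw["p_unadjusted"].iloc[0])

    def test_reference_tukey_probability(self):
        """k=3 family, t=2.67, df~1367: adjusted p near the classic 0.025."""
        from scipy.stats import studentized_range

        p = float(studentized_range.sf(2.67 * np.sqrt(2.0), 3, 1367))
        assert p == pytest.approx(0.025, abs=0.01)


class TestAnovaProperties:
    def test_df_bounds(self, small_fit):
        an = small_fit.anova()
        N, p = small_fit.model.N, small_fit.model.p
        assert (an["df_den"] <= N - p + 1e-9).all()
        assert (an["df_den"] >= min(small_fit.model.qp, small_fit.model.qf) - 1).all()
        assert (an["F"] >= 0).all()
        assert an["r2"].between(0, 1).all()

    def test_refit_via_set_response_matches_fresh_model(self, small_data):
        m1 = CrossedLMM.from_dataframe(small_data, value_col="value")
        r1 = m1.fit()
        y2 = small_data["value"].to_numpy() * 1.5 + 2.0
        r2 = m1.set_response(y2).fit()
        m3 = CrossedLMM.from_dataframe(small_data.assign(value=y2), value_col="value")
        r3 = m3.fit()
        assert r2.params == pytest.approx(r3.params, rel=1e-6)
        assert r2.vcomp["participant"] == pytest.approx(r3.vcomp["participant"], rel=1e-4)

    def test_summary_renders(self, small_fit):
        s = small_fit.summary()
        assert "Variance components" in s and "F tests" in s


class TestLmerTestOracle:
    def test_matches_r_lmerTest_and_emmeans(self, small_data, small_fit, tmp_path):
        """F, Satterthwaite df, p and Tukey contrasts agree with R to 4 decimals."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        csv = tmp_path / "d.csv"
        small_data.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages({{library(lmerTest); library(emmeans)}})
            d <- read.csv("{csv}")
            m <- lmer(value ~ emotion*condition + (1|participant_id) + (1|face_id), data=d)
            a <- anova(m)
            emm <- emmeans(m, ~ emotion | condition, lmer.df="satterthwaite")
            p <- summary(pairs(emm))
            cat(a$`F value`, a$DenDF, a$`Pr(>F)`, p$p.value, sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.split()]
        F_r, df_r, p_r, tukey_r = vals[0:3], vals[3:6], vals[6:9], vals[9:]
        an = small_fit.anova().loc[["emotion", "condition", "emotion:condition"]]
        assert np.allclose(an["F"], F_r, rtol=1e-4)
        assert np.allclose(an["df_den"], df_r, rtol=1e-3)
        assert np.allclose(an["p"], p_r, rtol=1e-3, atol=1e-6)
        pw = small_fit.pairwise("emotion", by="condition")
        assert np.allclose(pw["p_adjusted"].to_numpy(), tukey_r, atol=2e-4)
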