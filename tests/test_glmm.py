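import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from arstrack import SeparationError, fit_binomial_glmm, group_summary, r2_nakagawa


def simulate_logit_data(rng, n=800, n_groups=12, beta0=-1.0, beta1=1.5, sigma_b=1.0):
    g = rng.integers(0, n_groups, n)
    b = rng.normal(0.0, sigma_b, n_groups)
    x = rng.normal(0.0, 1.0, n)
    y = (rng.uniform(size=n) < expit(beta0 + beta1 * x + b[g])).astype(int)
    return pd.DataFrame({"boat_associated": y, "bird_id": g, "x": x})


class TestFitting:
    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(10)
        df = simulate_logit_data(rng, n=2000, n_groups=20)
        fit = fit_binomial_glmm(df, ["x"])
        assert fit.converged
        assert fit.params.loc["x", "coef"] == pytest.approx(1.5, rel=0.2)
        assert fit.sigma_b == pytest.approx(1.0, rel=0.45)

    def test_affine_shift_changes_only_intercept(self):
        rng = np.random.default_rng(11)
        df = simulate_logit_data(rng)
        fit_a = fit_binomial_glmm(df, ["x"])
        df2 = df.assign(x=df["x"] + 10.0)
        fit_b = fit_binomial_glmm(df2, ["x"])
        assert fit_b.params.loc["x", "coef"] == pytest.approx(
            fit_a.params.loc["x", "coef"], rel=0.02
        )
        assert fit_b.params.loc["(Intercept)", "coef"] == pytest.approx(
            fit_a.params.loc["(Intercept)", "coef"] - 10.0 * fit_a.params.loc["x", "coef"],
            rel=0.05, abs=0.1,
        )

    def test_degenerate_response_raises(self):
        df = pd.DataFrame(
            {"boat_associated": [0] * 40, "bird_id": [0, 1] * 20, "x": np.arange(40.0)}
        )
        with pytest.raises(SeparationError, match="degenerate"):
            fit_binomial_glmm(df, ["x"])

    def test_perfect_separation_raises(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=200)
        df = pd.DataFrame(
            {
                "boat_associated": (x > 0).astype(int),
                "bird_id": rng.integers(0, 5, 200),
                "x": x,
            }
        )
        with pytest.raises(SeparationError):
            fit_binomial_glmm(df, ["x"])

    def test_matches_lme4_glmer(self, tmp_path):
        """Independent cross-check against the reference mixed-model engine."""
        rng = np.random.default_rng(7)
        df = simulate_logit_data(rng)
        fit = fit_binomial_glmm(df, ["x"])

        csv = tmp_path / "d.csv"
        df.rename(columns={"boat_associated": "y", "bird_id": "g"}).to_csv(
            csv, index=False
        )
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|g), data=d, family=binomial)
            cf <- fixef(m)
            vc <- as.data.frame(VarCorr(m))
            cat(sprintf("%.6f %.6f %.6f", cf[1], cf[2], sqrt(vc$vcov[1])))
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, sig = map(float, out.stdout.split())
        assert fit.params.loc["(Intercept)", "coef"] == pytest.approx(b0, abs=0.02)
        assert fit.params.loc["x", "coef"] == pytest.approx(b1, abs=0.02)
        assert fit.sigma_b == pytest.approx(sig, abs=0.05)


class TestR2:
    def test_no_random_variance_marginal_equals_conditional(self):
        m, c = r2_nakagawa(0.8, 0.0)
        assert m == pytest.approx(c)

    def test_no_fixed_variance_marginal_zero(self):
        m, _ = r2_nakagawa(0.0, 1.3)
        assert m == 0.0

    def test_unit_variances_closed_form(self):
        m, c = r2_nakagawa(1.0, 1.0)
        assert m == pytest.approx(1.0 / (2.0 + np.pi**2 / 3.0), abs=1e-12)
        assert c == pytest.approx(2.0 / (2.0 + np.pi**2 / 3.0), abs=1e-12)

    def test_conditional_at_least_marginal(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            vf, vr = rng.uniform(0, 5, 2)
            m, c = r2_nakagawa(vf, vr)
            assert 0.0 <= m <= c <= 1.0


class TestGroupSummary:
    def _table(self):
        return pd.DataFrame(
            {
                "scale_class": ["small"] * 4 + ["large"],
                "boat_associated": [True, True, False, False, True],
                "duration_h": [4.0, 5.0, 2.0, 3.0, 30.0],
            }
        )

    def test_means_and_counts(self):
        out = group_summary(self._table(), ["duration_h"], ["scale_class", "boat_associated"])
        assert out.loc[("small", True), ("duration_h", "mean")] == pytest.approx(4.5)
        assert out.loc[("small", False), ("duration_h", "count")] == 2

    def test_single_row_stratum_sd_zero(self):
        out = group_summary(self._table(), ["duration_h"], ["scale_class", "boat_associated"])
        assert out.loc[("large", True), ("duration_h", "std")] == 0.0

    def test_row_order_invariance(self):
        t = self._table()
        a = group_summary(t, ["duration_h"], ["scale_class"])
        b = group_summary(t.iloc[::-1].reset_index(drop=True), ["duration_h"], ["scale_class"])
        pd.testing.assert_frame_equal(a, b)
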