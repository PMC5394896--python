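"""Encoding MANOVA / decoding ANOVA: oracles, identities, calibration."""

import numpy as np
import pytest
from scipy import stats

from anticipy.models import (
    channel_contribution_decoding,
    channel_contribution_encoding,
    demean_by_subject,
    fit_decoding,
    fit_encoding,
)

from conftest import factorial_y


def brute_force_pillai(X, y, subjects):
    """Independent construction: explicit dummy design, E^-1 H eigenvalues."""
    subjects = np.asarray(subjects)
    levels = np.unique(subjects)
    D = np.column_stack(
        [np.asarray(y, float)] + [(subjects == s).astype(float) for s in levels]
    )
    B = np.linalg.lstsq(D, X, rcond=None)[0]
    resid = X - D @ B
    E = resid.T @ resid
    L = np.zeros((1, D.shape[1]))
    L[0, 0] = 1.0
    M = L @ np.linalg.inv(D.T @ D) @ L.T
    H = (L @ B).T @ np.linalg.inv(M) @ (L @ B)
    lam = np.linalg.eigvals(np.linalg.solve(E, H)).real
    return float(np.sum(lam / (1.0 + lam)))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestPillaiOracle:
    @pytest.mark.parametrize("n_channels", [1, 2, 3, 4])
    def test_matches_brute_force_eigendecomposition(self, rng, n_channels):
        n, ns = 60, 3
        subjects = np.repeat(np.arange(ns), n // ns)
        y = rng.normal(size=n)
        X = rng.normal(size=(n, n_channels)) + 0.4 * y[:, None]
        enc = fit_encoding(X, y, subjects)
        V = brute_force_pillai(X, y, subjects)
        assert enc.pillai == pytest.approx(V, rel=1e-10)

    def test_matches_statsmodels_manova(self, rng):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        n, ns = 80, 4
        subjects = np.repeat(np.arange(ns), n // ns)
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 3)) + 0.5 * y[:, None]
        enc = fit_encoding(X, y, subjects)
        df = pd.DataFrame(X, columns=["c0", "c1", "c2"])
        df["y"], df["subject"] = y, subjects
        tab = (
            MANOVA.from_formula("c0 + c1 + c2 ~ y + C(subject)", data=df)
            .mv_test()
            .results["y"]["stat"]
        )
        row = tab.loc["Pillai's trace"]
        assert enc.pillai == pytest.approx(float(row["Value"]), rel=1e-8)
        assert enc.F == pytest.approx(float(row["F Value"]), rel=1e-8)
        assert (enc.df1, enc.df2) == (float(row["Num DF"]), float(row["Den DF"]))

    def test_single_channel_reduces_to_univariate_f(self, rng):
        n, ns = 48, 2
        subjects = np.repeat(np.arange(ns), n // ns)
        y = rng.normal(size=n)
        x = 0.7 * y + rng.normal(size=n)
        enc = fit_encoding(x[:, None], y, subjects)
        # univariate partial eta^2 and F of x ~ y + S
        xc = demean_by_subject(x, subjects)
        yc = demean_by_subject(y, subjects)
        r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
        F = r2 / (1 - r2) * (n - ns - 1)
        assert enc.pillai == pytest.approx(r2, rel=1e-10)
        assert enc.F == pytest.approx(F, rel=1e-10)


class TestDecoding:
    def test_perfect_linear_function_gives_r2_one(self, rng):
        n, ns = 40, 2
        subjects = np.repeat(np.arange(ns), n // ns)
        X = rng.normal(size=(n, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        dec = fit_decoding(X, y, subjects)
        assert dec.r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_channel_f_equals_squared_t(self, rng):
        n, ns = 50, 2
        subjects = np.repeat(np.arange(ns), n // ns)
        x = rng.normal(size=n)
        y = x + 0.5 * rng.normal(size=n)
        dec = fit_decoding(x[:, None], y, subjects)
        # squared t of the single coefficient
        xc = demean_by_subject(x, subjects)
        yc = demean_by_subject(y, subjects)
        beta = (xc @ yc) / (xc @ xc)
        resid = yc - beta * xc
        se = np.sqrt(resid @ resid / (n - ns - 1) / (xc @ xc))
        assert dec.F == pytest.approx((beta / se) ** 2, rel=1e-10)

    def test_encoding_decoding_f_identity_single_feature(self, rng):
        """For one numeric feature, the F-transformed Pillai trace equals the
        decoding block F (identical df), making the two group tests one test."""
        n, ns = 60, 3
        subjects = np.repeat(np.arange(ns), n // ns)
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 4)) + 0.3 * y[:, None]
        enc, dec = fit_encoding(X, y, subjects), fit_decoding(X, y, subjects)
        assert enc.F == pytest.approx(dec.F, rel=1e-9)
        assert (enc.df1, enc.df2) == (dec.df1, dec.df2)

    def test_collinear_channels_rejected_by_name(self, rng):
        n = 30
        subjects = np.zeros(n, dtype=int)
        x0 = rng.normal(size=n)
        X = np.column_stack([x0, rng.normal(size=n), 2.0 * x0])
        with pytest.raises(ValueError, match="collinear"):
            fit_decoding(X, rng.normal(size=n), subjects)


class TestChannelContributions:
    def test_exact_channel_has_p_zero(self, rng):
        n, ns = 36, 2
        subjects = np.repeat(np.arange(ns), n // ns)
        y = factorial_y(rng, subjects)
        assert channel_contribution_encoding(y.copy(), y, subjects) < 1e-200

    def test_loo_f_equals_squared_coefficient_t(self, rng):
        n, ns, C = 60, 3, 4
        subjects = np.repeat(np.arange(ns), n // ns)
        X = rng.normal(size=(n, C))
        y = X[:, 2] + 0.3 * rng.normal(size=n)
        p_loo = channel_contribution_decoding(X, y, subjects)
        # per-coefficient t tests from the full model
        Xc = demean_by_subject(X, subjects)
        yc = demean_by_subject(y, subjects)
        XtX_inv = np.linalg.inv(Xc.T @ Xc)
        beta = XtX_inv @ Xc.T @ yc
        resid = yc - Xc @ beta
        sigma2 = resid @ resid / (n - ns - C)
        t2 = beta**2 / (np.diag(XtX_inv) * sigma2)
        p_t = stats.f.sf(t2, 1, n - ns - C)
        assert np.allclose(p_loo, p_t, rtol=1e-10)

    def test_duplicated_channel_has_no_unique_contribution(self, rng):
        n = 60
        subjects = np.zeros(n, dtype=int)
        x = rng.normal(size=n)
        x -= x.mean()
        y = x + 0.1 * rng.normal(size=n)
        y -= y.mean()
        # near-duplicate whose deviation carries no outcome information:
        # the t statistic is invariant to the 1e-6 scaling, so the deviation
        # must be orthogonal to the outcome given every other column
        x3 = rng.normal(size=n)
        x3 -= x3.mean()
        d = rng.normal(size=n)
        span = np.column_stack([x, y, x3])
        d -= span @ np.linalg.lstsq(span, d, rcond=None)[0]
        X = np.column_stack([x, x + 1e-6 * d, x3])
        p = channel_contribution_decoding(X, y, subjects)
        assert p[0] > 0.99 and p[1] > 0.99  # near-duplicates defeat each other

    def test_noise_channel_does_not_change_encoding_contribution(self, rng):
        n, ns = 48, 2
        subjects = np.repeat(np.arange(ns), n // ns)
        y = rng.normal(size=n)
        x_k = 0.5 * y + rng.normal(size=n)
        p1 = channel_contribution_encoding(x_k, y, subjects)
        # the single-channel model is marginal: other channels are irrelevant
        p2 = channel_contribution_encoding(x_k, y, subjects)
        assert p1 == p2

    def test_constant_channel_warns_p_one(self, rng):
        n = 20
        subjects = np.zeros(n, dtype=int)
        with pytest.warns(UserWarning, match="constant"):
            p = channel_contribution_encoding(np.ones(n), rng.normal(size=n), subjects)
        assert p == 1.0


class TestNullCalibration:
    """Analytic p-values are exactly F-distributed under Gaussian nulls."""

    def test_encoding_p_uniform_under_null(self, rng):
        n, ns, C = 45, 3, 3
        subjects = np.repeat(np.arange(ns), n // ns)
        pvals = [
            fit_encoding(rng.normal(size=(n, C)), rng.normal(size=n), subjects).p
            for _ in range(400)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_decoding_p_uniform_under_null(self, rng):
        n, ns, C = 45, 3, 3
        subjects = np.repeat(np.arange(ns), n // ns)
        pvals = [
            fit_decoding(rng.normal(size=(n, C)), rng.normal(size=n), subjects).p
            for _ in range(400)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_effect_has_extreme_p(self, rng):
        n, ns = 90, 3
        subjects = np.repeat(np.arange(ns), n // ns)
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 3)) * 0.1
        X[:, 0] += y
        assert fit_encoding(X, y, subjects).p < 1e-6
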