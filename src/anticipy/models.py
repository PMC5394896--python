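"""Per-time-bin group-level encoding and decoding models.

All models are fitted on trials concatenated across subjects, with fixed
per-subject intercepts.  The encoding model is the multivariate linear
model X ~ Y + S tested on the F-transformed Pillai-Bartlett trace; the
decoding model is the univariate regression Y ~ X + S tested with a
block F test on the channel coefficients.  Channel contributions are a
single-channel regression X_k ~ Y + S (encoding) and a leave-one-out
nested F test (decoding).

Because subject intercepts are the only nuisance terms, fitting reduces
to ordinary least squares on subject-demeaned variables; degrees of
freedom account for the absorbed intercepts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EncodingFit",
    "DecodingFit",
    "demean_by_subject",
    "pillai_f",
    "fit_encoding",
    "fit_decoding",
    "channel_contribution_encoding",
    "channel_contribution_decoding",
]


@dataclass(frozen=True)
class EncodingFit:
    pillai: float
    F: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class DecodingFit:
    F: float
    df1: float
    df2: float
    p: float
    r2: float  # partial R^2 of the channel block given subject intercepts


def demean_by_subject(a: np.ndarray, subjects: np.ndarray) -> np.ndarray:
    """Residualize on per-subject intercepts (subtract subject means, axis 0)."""
    a = np.asarray(a, float)
    subjects = np.asarray(subjects)
    _, inv = np.unique(subjects, return_inverse=True)
    n_groups = inv.max() + 1
    counts = np.bincount(inv, minlength=n_groups).astype(float)
    if a.ndim == 1:
        sums = np.bincount(inv, weights=a, minlength=n_groups)
        return a - (sums / counts)[inv]
    flat = a.reshape(len(a), -1)
    means = np.zeros((n_groups, flat.shape[1]))
    np.add.at(means, inv, flat)
    means /= counts[:, None]
    return (flat - means[inv]).reshape(a.shape)


def _n_subjects(subjects) -> int:
    return len(np.unique(subjects))


def _as_2d(y) -> np.ndarray:
    y = np.asarray(y, float)
    return y[:, None] if y.ndim == 1 else y


def _check_design(n, p, n_sub, q):
    if n < p + n_sub + q + 1:
        raise ValueError(
            f"too few trials ({n}) for {p} channels, {n_sub} subject intercepts "
            f"and {q} feature column(s)"
        )


def _check_rank(Xc: np.ndarray) -> None:
    """Error naming collinear channel columns (QR with column pivoting)."""
    from scipy.linalg import qr

    p = Xc.shape[1]
    if np.linalg.matrix_rank(Xc) < p:
        _, r, piv = qr(Xc, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        tol = d.max() * max(Xc.shape) * np.finfo(float).eps
        bad = sorted(int(piv[i]) for i in range(p) if i >= len(d) or d[i] < tol)
        raise ValueError(f"rank-deficient data matrix; collinear channels: {bad}")


def pillai_f(V: float, p: int, q: int, df_error: int):
    """F approximation for the Pillai-Bartlett trace.

    p = number of response channels, q = hypothesis df, df_error = error df
    of the multivariate model.  Returns (F, df1, df2).
    """
    s = min(p, q)
    m = (abs(p - q) - 1.0) / 2.0
    n_ = (df_error - p - 1.0) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    denom = s - V
    if denom <= 0:
        return np.inf, df1, df2
    F = (V / denom) * (df2 / df1)
    return F, df1, df2


def fit_encoding(X: np.ndarray, y, subjects) -> EncodingFit:
    """MANOVA of channels on a stimulus feature with subject intercepts.

    X : (trials, channels); y : (trials,) numeric feature or (trials, q)
    feature design (q > 1 for categorical coding).  The test statistic is
    the Pillai-Bartlett trace of the feature term, F-transformed.
    """
    X = np.asarray(X, float)
    Y = _as_2d(y)
    n, p = X.shape
    q = Y.shape[1]
    n_sub = _n_subjects(subjects)
    _check_design(n, p, n_sub, q)

    Xc = demean_by_subject(X, subjects)
    Yc = demean_by_subject(Y, subjects)
    _check_rank(Xc)
    if np.allclose(Yc, 0):
        raise ValueError("feature is constant within subjects; MANOVA degenerate")

    # Hypothesis and error cross-products for the feature term.
    G = np.linalg.solve(Yc.T @ Yc, Yc.T @ Xc)  # (q, p) coefficients
    H = (Yc @ G).T @ (Yc @ G)
    T = Xc.T @ Xc
    E = T - H
    lam = np.linalg.eigvals(np.linalg.solve(E, H))
    lam = np.clip(lam.real, 0.0, None)
    V = float(np.sum(lam / (1.0 + lam)))

    df_error = n - n_sub - q
    F, df1, df2 = pillai_f(V, p, q, df_error)
    pval = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return EncodingFit(pillai=V, F=float(F), df1=df1, df2=df2, p=pval)


def fit_decoding(X: np.ndarray, y, subjects) -> DecodingFit:
    """Regression of the feature on all channels with subject intercepts.

    The channel block is tested against the intercept-only model with a
    standard F test; r2 is the partial R^2 of the block.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    n_sub = _n_subjects(subjects)
    _check_design(n, p, n_sub, 1)

    Xc = demean_by_subject(X, subjects)
    yc = demean_by_subject(y, subjects)
    _check_rank(Xc)

    sst = float(yc @ yc)
    if sst <= 0:
        raise ValueError("feature is constant within subjects")
    beta, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    rss = float(resid @ resid)
    df2 = n - n_sub - p
    F = ((sst - rss) / p) / (rss / df2)
    r2 = 1.0 - rss / sst
    return DecodingFit(F=float(F), df1=p, df2=df2, p=float(stats.f.sf(F, p, df2)), r2=r2)


def channel_contribution_encoding(x_k: np.ndarray, y, subjects) -> float:
    """p-value of the feature term in the single-channel model X_k ~ Y + S."""
    x_k = np.asarray(x_k, float).ravel()
    Y = _as_2d(y)
    n = len(x_k)
    q = Y.shape[1]
    n_sub = _n_subjects(subjects)
    xc = demean_by_subject(x_k, subjects)
    Yc = demean_by_subject(Y, subjects)
    sst = float(xc @ xc)
    if sst <= 0:
        warnings.warn("constant channel; contribution p set to 1", stacklevel=2)
        return 1.0
    beta, _, _, _ = np.linalg.lstsq(Yc, xc, rcond=None)
    resid = xc - Yc @ beta
    rss = float(resid @ resid)
    df2 = n - n_sub - q
    if rss <= 0:
        return 0.0
    F = ((sst - rss) / q) / (rss / df2)
    return float(stats.f.sf(F, q, df2))


def channel_contribution_decoding(X: np.ndarray, y, subjects, k: int | None = None):
    """Leave-one-channel-out F test against the full decoding model.

    Returns the p-value for channel ``k``, or the vector of p-values for
    all channels when ``k`` is None.  With one numerator df the F equals
    the square of the channel coefficient's t statistic.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    n_sub = _n_subjects(subjects)
    _check_design(n, p, n_sub, 1)
    Xc = demean_by_subject(X, subjects)
    yc = demean_by_subject(y, subjects)
    _check_rank(Xc)

    XtX = Xc.T @ Xc
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xc.T @ yc)
    resid = yc - Xc @ beta
    rss = float(resid @ resid)
    df2 = n - n_sub - p
    sigma2 = rss / df2
    # RSS increase from dropping channel j: beta_j^2 / (X'X)^-1_jj
    F_all = beta**2 / (np.diag(XtX_inv) * sigma2)
    p_all = stats.f.sf(F_all, 1, df2)
    if k is None:
        return p_all
    return float(p_all[k])
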