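"""Temporal generalization: cross-prediction of every bin from every bin.

The encoding model fitted at a source time bin (feature pattern over
channels, subject intercepts refitted at the target) is scored on target
data from every other bin.  Explained variance is the multivariate
R^2 = 1 - SSR/SST pooled over channels about subject means, which is
negative when a model mispredicts.  Per target bin, trial labels are
permuted to obtain a null for each matrix entry; entries that are
non-significant or negative are set to zero.  Temporal stability is
quantified by comparing off-diagonal cross-prediction mass between the
two halves of the anticipation window, against a null that permutes the
time labels of the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .inference import _within_subject_perms
from .models import demean_by_subject
from .preprocess import BinnedDataset

__all__ = [
    "CrossPredMatrix",
    "StabilityResult",
    "cross_predict",
    "cross_predict_between_features",
    "stability_statistic",
    "normalize_by_source_fit",
]


@dataclass
class CrossPredMatrix:
    ev: np.ndarray  # (source bins, target bins) explained variance
    p: np.ndarray  # permutation p-values, same shape
    ev_thresholded: np.ndarray  # zeroed where p > p_threshold or ev < 0
    bin_centers_ms: np.ndarray
    p_threshold: float = 0.05
    normalized: bool = False
    zero_diag_rows: tuple = ()

    @property
    def n_bins(self) -> int:
        return self.ev.shape[0]


@dataclass
class StabilityResult:
    statistic: float  # off-diagonal mass, second half minus first half
    p: float
    diag_statistic: float
    diag_p: float
    split_ms: float
    n_perm: int
    alternative: str = "greater"


def _core_cross_predict(
    Xc_bins: np.ndarray,  # (n, C, B) subject-demeaned data
    y_fit_c: np.ndarray,  # subject-demeaned fitting feature
    y_eval_c: np.ndarray,  # subject-demeaned evaluation feature
    subjects: np.ndarray,
    centers: np.ndarray,
    seed: int,
    n_perm_trial: int,
    p_threshold: float,
) -> CrossPredMatrix:
    n, C, B = Xc_bins.shape
    if n <= C + 1:
        raise ValueError("fewer trials than model parameters at the target bins")
    yy_fit = float(y_fit_c @ y_fit_c)
    yy_eval = float(y_eval_c @ y_eval_c)
    if yy_fit <= 0 or yy_eval <= 0:
        raise ValueError("feature constant within subjects")

    # Per-bin feature patterns (channel coefficients of the encoding model)
    Bmat = np.einsum("ncb,n->bc", Xc_bins, y_fit_c) / yy_fit  # (B, C)
    bnorm2 = (Bmat**2).sum(axis=1)  # |b_s|^2 per source bin

    sst = np.einsum("ncb,ncb->b", Xc_bins, Xc_bins)  # (B,)
    G = np.einsum("ncb,n->bc", Xc_bins, y_eval_c)  # (B targets, C)
    # EV(s, t) = (2 g_t . b_s - yy_eval |b_s|^2) / SST_t
    ev = (2.0 * (G @ Bmat.T) - yy_eval * bnorm2[None, :]) / sst[:, None]
    ev = ev.T  # (source, target)

    rng = np.random.default_rng(seed)
    perms = _within_subject_perms(subjects, n_perm_trial, rng)
    Yp = y_eval_c[perms]  # (P, n)
    exceed = np.zeros((B, B), dtype=np.int64)  # (source, target)
    for t in range(B):
        cross = Yp @ Xc_bins[:, :, t]  # (P, C)
        ev_null = (2.0 * (cross @ Bmat.T) - yy_eval * bnorm2[None, :]) / sst[t]
        exceed[:, t] = (ev_null >= ev[:, t][None, :]).sum(axis=0)
    pmat = (1.0 + exceed) / (n_perm_trial + 1.0)

    thr = ev.copy()
    thr[(pmat > p_threshold) | (ev < 0)] = 0.0
    return CrossPredMatrix(
        ev=ev,
        p=pmat,
        ev_thresholded=thr,
        bin_centers_ms=np.asarray(centers, float),
        p_threshold=p_threshold,
    )


def cross_predict(
    binned: BinnedDataset,
    y,
    subjects=None,
    seed: int = 0,
    n_perm_trial: int = 1000,
    p_threshold: float = 0.05,
) -> CrossPredMatrix:
    """Bins x bins explained-variance matrix with permutation p-values.

    The diagonal equals the in-bin encoding fit.  Trial-label permutations
    (within subject) at the target bin provide the per-entry null.
    """
    if n_perm_trial < 100:
        raise ValueError("n_perm_trial must be >= 100")
    subjects = binned.subject if subjects is None else np.asarray(subjects)
    yc = demean_by_subject(np.asarray(y, float).ravel(), subjects)
    Xc = demean_by_subject(binned.data, subjects)
    return _core_cross_predict(
        Xc, yc, yc, subjects, binned.bin_centers_ms, seed, n_perm_trial, p_threshold
    )


def cross_predict_between_features(
    binned: BinnedDataset,
    y_fit,
    y_eval,
    subjects=None,
    seed: int = 0,
    n_perm_trial: int = 1000,
    p_threshold: float = 0.05,
) -> CrossPredMatrix:
    """Score models fitted on one feature against data arranged by another.

    Used to check that, e.g., mean-reward models do not explain data coded
    by (possibly sign-flipped) variability.  With ``y_eval`` identical to
    ``y_fit`` this reduces exactly to :func:`cross_predict`.
    """
    if n_perm_trial < 100:
        raise ValueError("n_perm_trial must be >= 100")
    subjects = binned.subject if subjects is None else np.asarray(subjects)
    yf = demean_by_subject(np.asarray(y_fit, float).ravel(), subjects)
    ye = demean_by_subject(np.asarray(y_eval, float).ravel(), subjects)
    Xc = demean_by_subject(binned.data, subjects)
    return _core_cross_predict(
        Xc, yf, ye, subjects, binned.bin_centers_ms, seed, n_perm_trial, p_threshold
    )


def _block_sums(M: np.ndarray, labels: np.ndarray):
    """Off-diagonal sums within the label-0 and label-1 blocks."""
    d = np.diag(M)
    out = []
    for k in (0, 1):
        v = (labels == k).astype(float)
        out.append(float(v @ M @ v - d @ v))
    return out[0], out[1]


def stability_statistic(
    xpm: CrossPredMatrix,
    split_ms: float = 1000.0,
    n_perm_time: int = 100_000,
    seed: int = 0,
    alternative: str = "greater",
) -> StabilityResult:
    """Half-window stability test on the thresholded cross-prediction matrix.

    The statistic sums off-diagonal entries whose source and target bins
    both lie in the second half of the window and subtracts the first-half
    block sum.  The null jointly permutes the time labels of rows and
    columns (``n_perm_time`` draws); the same machinery is applied to the
    diagonal to score in-bin encoding strength.
    """
    if n_perm_time < 1000:
        raise ValueError("n_perm_time must be >= 1000")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    M = xpm.ev_thresholded
    B = M.shape[0]
    labels = (xpm.bin_centers_ms >= split_ms).astype(int)
    if labels.min() == labels.max():
        raise ValueError("split_ms puts all bins in one half")
    d = np.diag(M).copy()

    s1, s2 = _block_sums(M, labels)
    stat = s2 - s1
    diag_stat = float(d[labels == 1].sum() - d[labels == 0].sum())

    degenerate = not np.any(M)
    if degenerate:
        warnings.warn("all-zero cross-prediction matrix; p = 1", stacklevel=2)
        return StabilityResult(stat, 1.0, diag_stat, 1.0, split_ms, n_perm_time, alternative)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm_time)
    null_diag = np.empty(n_perm_time)
    chunk = max(1, min(n_perm_time, 20_000_000 // (B * B + 1)))
    Md = M - np.diag(d)
    done = 0
    while done < n_perm_time:
        m = min(chunk, n_perm_time - done)
        V = np.empty((m, B))
        for r in range(m):
            V[r] = labels[rng.permutation(B)]
        # off-diagonal block sums under permuted labels
        s2_null = np.einsum("rb,bc,rc->r", V, Md, V)
        U = 1.0 - V
        s1_null = np.einsum("rb,bc,rc->r", U, Md, U)
        null[done : done + m] = s2_null - s1_null
        null_diag[done : done + m] = V @ d - U @ d
        done += m

    def pval(obs, ns):
        if alternative == "greater":
            return (1.0 + float((ns >= obs).sum())) / (len(ns) + 1.0)
        return (1.0 + float((np.abs(ns) >= abs(obs)).sum())) / (len(ns) + 1.0)

    return StabilityResult(
        statistic=float(stat),
        p=pval(stat, null),
        diag_statistic=diag_stat,
        diag_p=pval(diag_stat, null_diag),
        split_ms=split_ms,
        n_perm=n_perm_time,
        alternative=alternative,
    )


def normalize_by_source_fit(xpm: CrossPredMatrix) -> CrossPredMatrix:
    """Divide each row by the in-bin fit (diagonal) of its source model.

    Rows are normalized only where the source model has a significant
    positive in-bin fit (nonzero thresholded diagonal); dividing by a
    noise-level diagonal would only amplify noise.  Remaining rows are
    left as zero and flagged in ``zero_diag_rows``.
    """
    diag = np.diag(xpm.ev).copy()
    ok = np.diag(xpm.ev_thresholded) > 0
    ev = np.zeros_like(xpm.ev)
    thr = np.zeros_like(xpm.ev_thresholded)
    ev[ok] = xpm.ev[ok] / diag[ok, None]
    thr[ok] = xpm.ev_thresholded[ok] / diag[ok, None]
    return replace(
        xpm,
        ev=ev,
        ev_thresholded=thr,
        normalized=True,
        zero_diag_rows=tuple(np.flatnonzero(~ok).tolist()),
    )
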