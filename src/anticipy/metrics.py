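"""AIC comparison of reward-variability metrics and feature preference.

Candidate variability metrics are the coefficient of variation (CV),
the outcome standard deviation (SD) and the variance (V).  In a design
crossing mean reward with CV, SD and V are correlated with mean level
(SD = CV * mean, V = SD^2) and are therefore decorrelated by removing
the metric's mean within each mean-reward level before model fitting.
Encoding models with each metric as predictor are compared through AIC
computed from residual sums of squares; a metric (or feature) is
declared preferred only when the summed AIC difference exceeds 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import demean_by_subject
from .preprocess import BinnedDataset

__all__ = [
    "AIC_PREFERENCE_MARGIN",
    "metric_values",
    "decorrelate_metric",
    "aic_from_rss",
    "ModelEvidence",
    "compare_variability_metrics",
    "preferential_encoding",
]

AIC_PREFERENCE_MARGIN = 3.0


def metric_values(stim: pd.DataFrame, name: str, decorrelate: bool = True) -> np.ndarray:
    """Per-trial values of a variability metric from the stimulus table.

    name : 'CV', 'SD' or 'V'.  SD and V are decorrelated from mean reward
    by default; CV is orthogonal to mean level in a balanced design and is
    returned as is.
    """
    cv = stim["cv"].to_numpy(float)
    mean = stim["mean_reward"].to_numpy(float)
    if name == "CV":
        return cv
    if name == "SD":
        vals = cv * mean
    elif name == "V":
        vals = (cv * mean) ** 2
    else:
        raise ValueError(f"unknown metric {name!r}")
    return decorrelate_metric(vals, mean) if decorrelate else vals


def decorrelate_metric(values: np.ndarray, mean_level: np.ndarray) -> np.ndarray:
    """Subtract the metric's mean within each mean-reward level.

    The result has exactly zero mean within every level and is therefore
    uncorrelated with any function of mean level.  Idempotent.
    """
    values = np.asarray(values, float)
    mean_level = np.asarray(mean_level)
    out = values.copy()
    for lv in np.unique(mean_level):
        m = mean_level == lv
        out[m] -= out[m].mean()
    return out


def aic_from_rss(rss: float, n: int, k: int) -> float:
    """Gaussian-likelihood AIC from a residual sum of squares.

    AIC = n ln(rss/n) + 2k, with the additive constant n(ln(2 pi) + 1)
    omitted consistently so that only differences are meaningful.
    """
    if n <= k:
        raise ValueError("need more observations than parameters")
    if rss <= 0:
        raise ValueError("rss must be positive (perfect fit has no finite AIC)")
    return n * math.log(rss / n) + 2 * k


@dataclass
class ModelEvidence:
    """Summed AIC per candidate model with the pairwise preference rule."""

    aic: dict  # model name -> summed AIC
    per_bin: pd.DataFrame  # columns: bin, model, rss, aic
    n_obs: int
    k: int

    @property
    def winner(self) -> str | None:
        """Best model, or None when the AIC margin is not met."""
        ranked = sorted(self.aic.items(), key=lambda kv: kv[1])
        if len(ranked) > 1 and ranked[1][1] - ranked[0][1] <= AIC_PREFERENCE_MARGIN:
            return None
        return ranked[0][0]

    def delta(self, a: str, b: str) -> float:
        return self.aic[a] - self.aic[b]


def _bin_rss_multivariate(Xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Pooled residual SS (trace of residual cross-product) per bin.

    Xc : (n, C, B) subject-demeaned data, yc subject-demeaned predictor.
    """
    yy = float(yc @ yc)
    g = np.einsum("ncb,n->cb", Xc, yc)  # (C, B)
    sst = np.einsum("ncb,ncb->b", Xc, Xc)
    return sst - (g**2).sum(axis=0) / yy


def _bin_rss_single(xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Residual SS per bin for one channel: xc (n, B)."""
    yy = float(yc @ yc)
    g = xc.T @ yc  # (B,)
    sst = (xc**2).sum(axis=0)
    return sst - g**2 / yy


def compare_variability_metrics(
    binned: BinnedDataset,
    stim: pd.DataFrame,
    subjects=None,
    scope: str = "pooled",
    bins=None,
) -> ModelEvidence | pd.DataFrame:
    """AIC comparison of CV vs decorrelated SD vs decorrelated V.

    scope='pooled' accumulates the multivariate residual SS over all
    channels and returns a single :class:`ModelEvidence`; scope='per-channel'
    runs single-channel encoding regressions and returns a DataFrame with
    one row per channel (best metric under the AIC margin rule, or None).
    ``bins`` restricts the sum to the given bin indices (e.g. the
    cluster-significant bins); default all bins.
    """
    if scope not in ("pooled", "per-channel"):
        raise ValueError("scope must be 'pooled' or 'per-channel'")
    subjects = binned.subject if subjects is None else np.asarray(subjects)
    bins = np.arange(binned.n_bins) if bins is None else np.asarray(bins)
    n, C = binned.n_trials, binned.n_channels
    n_sub = len(np.unique(subjects))
    Xc = demean_by_subject(binned.data[:, :, bins], subjects)

    predictors = {
        name: demean_by_subject(metric_values(stim, name), subjects)
        for name in ("CV", "SD", "V")
    }

    if scope == "pooled":
        n_obs = n * C
        k = C * (n_sub + 1)
        rows, aic = [], {}
        for name, yc in predictors.items():
            rss = _bin_rss_multivariate(Xc, yc)
            aics = [aic_from_rss(r, n_obs, k) for r in rss]
            aic[name] = float(np.sum(aics))
            rows += [
                {"bin": int(b), "model": name, "rss": float(r), "aic": a}
                for b, r, a in zip(bins, rss, aics)
            ]
        return ModelEvidence(aic=aic, per_bin=pd.DataFrame(rows), n_obs=n_obs, k=k)

    k = n_sub + 1
    out = []
    for c in range(C):
        xc = Xc[:, c, :]
        aic = {}
        for name, yc in predictors.items():
            rss = _bin_rss_single(xc, yc)
            aic[name] = float(sum(aic_from_rss(r, n, k) for r in rss))
        ranked = sorted(aic.items(), key=lambda kv: kv[1])
        best = (
            ranked[0][0]
            if ranked[1][1] - ranked[0][1] > AIC_PREFERENCE_MARGIN
            else None
        )
        out.append({"channel": c, "best_metric": best, **{f"aic_{m}": v for m, v in aic.items()}})
    return pd.DataFrame(out)


def preferential_encoding(
    binned: BinnedDataset,
    stim: pd.DataFrame,
    subjects=None,
    variability_metric: str = "CV",
    bins=None,
) -> pd.DataFrame:
    """Per-channel preference for mean reward (Mag) vs variability (Var).

    For every channel, single-channel encoding AICs are summed across the
    analyzed bins for a mean-reward predictor and a variability predictor;
    the preference is declared only when |delta AIC| > 3, else 'none'.
    """
    subjects = binned.subject if subjects is None else np.asarray(subjects)
    bins = np.arange(binned.n_bins) if bins is None else np.asarray(bins)
    n = binned.n_trials
    n_sub = len(np.unique(subjects))
    k = n_sub + 1
    Xc = demean_by_subject(binned.data[:, :, bins], subjects)
    y_mag = demean_by_subject(stim["mean_reward"].to_numpy(float), subjects)
    y_var = demean_by_subject(metric_values(stim, variability_metric), subjects)

    rows = []
    for c in range(binned.n_channels):
        xc = Xc[:, c, :]
        aic_mag = float(sum(aic_from_rss(r, n, k) for r in _bin_rss_single(xc, y_mag)))
        aic_var = float(sum(aic_from_rss(r, n, k) for r in _bin_rss_single(xc, y_var)))
        d = aic_mag - aic_var
        if d < -AIC_PREFERENCE_MARGIN:
            pref = "Mag"
        elif d > AIC_PREFERENCE_MARGIN:
            pref = "Var"
        else:
            pref = "none"
        rows.append(
            {
                "channel": c,
                "preference": pref,
                "aic_mean": aic_mag,
                "aic_variability": aic_var,
                "delta_aic": d,
            }
        )
    return pd.DataFrame(rows)
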