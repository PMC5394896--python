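"""Cluster-level permutation correction over time and causal channel labels.

Multiple comparisons across time bins are controlled with a cluster-level
permutation test: candidate clusters are maximal runs of consecutive bins
whose per-bin test is below the cluster-forming threshold, the cluster
statistic is the mass (sum of bin F values), and the null distribution is
the maximum cluster mass under within-subject permutation of trial labels.

Channel labels combine the per-channel encoding contribution p-value and
the leave-one-out decoding p-value:

=====================  =====================  ================
encoding contribution  decoding contribution  label
=====================  =====================  ================
p < alpha              p < alpha              direct
p < alpha              alpha < p <= 0.10      possible_direct
p < alpha              p > 0.10               indirect
alpha < p <= 0.10      p < alpha              possible_direct
p > 0.10               p < alpha              context
otherwise                                     undetermined
=====================  =====================  ================

A channel significant in encoding but not decoding relates to the feature
only through another channel (indirect); one that improves decoding
without itself encoding tracks the noise of an encoding channel ("brain
state context").  Channels are only labelled in bins where the overall
multivariate model survives cluster correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    channel_contribution_decoding,
    channel_contribution_encoding,
    demean_by_subject,
)
from .preprocess import BinnedDataset

__all__ = [
    "ClusterResult",
    "cluster_permutation",
    "classify_channel",
    "classify_all",
    "LABELS",
]

LABELS = ("direct", "possible_direct", "indirect", "context", "undetermined")


@dataclass
class ClusterResult:
    bin_stats: np.ndarray  # per-bin F
    bin_p: np.ndarray  # per-bin uncorrected p
    clusters: list  # (start_bin, end_bin_inclusive, mass, p)
    mask: np.ndarray  # bins inside clusters with p < alpha
    alpha: float
    cluster_alpha: float
    n_perm: int

    @property
    def significant_bins(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def _find_clusters(pvals: np.ndarray, fvals: np.ndarray, cluster_alpha: float):
    """Maximal runs of consecutive supra-threshold bins with their mass."""
    supra = pvals < cluster_alpha
    clusters = []
    i = 0
    n = len(supra)
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1]:
                j += 1
            clusters.append((i, j, float(fvals[i : j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return clusters


def _within_subject_perms(subjects: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """(n_perm, n) index arrays permuting trials within each subject."""
    n = len(subjects)
    perms = np.tile(np.arange(n), (n_perm, 1))
    for s in np.unique(subjects):
        idx = np.flatnonzero(subjects == s)
        for r in range(n_perm):
            perms[r, idx] = idx[rng.permutation(len(idx))]
    return perms


def _bin_f_traces(Q: np.ndarray, yc: np.ndarray, n: int, n_sub: int, p: int):
    """F and p per bin from orthonormal channel bases Q (bins, n, p).

    For a single numeric feature the F-transformed Pillai trace of the
    encoding MANOVA and the decoding block F coincide; both equal
    (R2 / (1 - R2)) * (n - n_sub - p) / p where R2 = |Q' y|^2 / |y|^2.
    """
    yy = float(yc @ yc)
    proj = np.einsum("bnc,n->bc", Q, yc)
    r2 = (proj**2).sum(axis=1) / yy
    df2 = n - n_sub - p
    F = (r2 / np.clip(1.0 - r2, 1e-300, None)) * (df2 / p)
    pv = stats.f.sf(F, p, df2)
    return F, pv


def cluster_permutation(
    binned: BinnedDataset,
    y,
    subjects=None,
    model: str = "encoding",
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-corrected significance of the per-bin group model over time.

    ``y`` is the numeric feature vector.  Trial labels are permuted within
    subject; the null statistic is the maximum cluster mass per
    permutation, and cluster p-values use add-one smoothing.  For a single
    numeric feature the encoding and decoding traces are identical (see
    :func:`_bin_f_traces`), so ``model`` only records intent.
    """
    if model not in ("encoding", "decoding"):
        raise ValueError("model must be 'encoding' or 'decoding'")
    if not 0 < cluster_alpha < 1 or not 0 < alpha < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    subjects = binned.subject if subjects is None else np.asarray(subjects)
    y = np.asarray(y, float).ravel()
    if np.all(y == y[0]):
        raise ValueError("feature labels are constant; permutation test degenerate")

    data = binned.data  # (n, p, B)
    n, p, B = data.shape
    n_sub = len(np.unique(subjects))
    yc = demean_by_subject(y, subjects)
    Xc = demean_by_subject(data, subjects)

    Q = np.empty((B, n, p))
    for b in range(B):
        Q[b], _ = np.linalg.qr(Xc[:, :, b])

    F_obs, p_obs = _bin_f_traces(Q, yc, n, n_sub, p)
    clusters = _find_clusters(p_obs, F_obs, cluster_alpha)

    rng = np.random.default_rng(seed)
    perms = _within_subject_perms(subjects, n_perm, rng)
    null_max = np.zeros(n_perm)
    df2 = n - n_sub - p
    yy = float(yc @ yc)
    Yp = yc[perms]  # (n_perm, n)
    # projections for all permutations and bins at once
    proj = np.einsum("bnc,rn->rbc", Q, Yp)
    r2 = (proj**2).sum(axis=2) / yy  # (n_perm, B)
    Fn = (r2 / np.clip(1.0 - r2, 1e-300, None)) * (df2 / p)
    pn = stats.f.sf(Fn, p, df2)
    for r in range(n_perm):
        cl = _find_clusters(pn[r], Fn[r], cluster_alpha)
        null_max[r] = max((m for _, _, m in cl), default=0.0)

    out = []
    mask = np.zeros(B, dtype=bool)
    for start, end, mass in clusters:
        pval = (1.0 + float((null_max >= mass).sum())) / (n_perm + 1.0)
        out.append((start, end, mass, pval))
        if pval < alpha:
            mask[start : end + 1] = True
    return ClusterResult(
        bin_stats=F_obs,
        bin_p=p_obs,
        clusters=out,
        mask=mask,
        alpha=alpha,
        cluster_alpha=cluster_alpha,
        n_perm=n_perm,
    )


def classify_channel(
    p_enc: float, p_dec: float, alpha: float = 0.05, margin: float = 0.10
) -> str:
    """Causal label from paired encoding/decoding contribution p-values.

    "Significant" is p < alpha strictly; the indeterminate band is
    (alpha, margin], with p == alpha counting as non-significant and
    p == margin falling inside the band.
    """
    enc_sig = p_enc < alpha
    dec_sig = p_dec < alpha
    if enc_sig and dec_sig:
        return "direct"
    if enc_sig:
        return "possible_direct" if p_dec <= margin else "indirect"
    if dec_sig:
        return "possible_direct" if p_enc <= margin else "context"
    return "undetermined"


def classify_all(
    binned: BinnedDataset,
    y,
    subjects=None,
    cluster: ClusterResult | None = None,
    alpha: float = 0.05,
    margin: float = 0.10,
) -> pd.DataFrame:
    """Label every (bin, channel) pair; long-format DataFrame.

    Channel tests run only in cluster-significant bins; all other bins are
    labelled undetermined with NaN p-values.
    """
    if cluster is None:
        raise ValueError("a ClusterResult for the feature is required")
    subjects = binned.subject if subjects is None else np.asarray(subjects)
    y = np.asarray(y, float).ravel()
    rows = []
    sig = set(cluster.significant_bins.tolist())
    for b in range(binned.n_bins):
        if b in sig:
            Xb = binned.data[:, :, b]
            p_dec_all = channel_contribution_decoding(Xb, y, subjects)
            for k in range(binned.n_channels):
                p_enc = channel_contribution_encoding(Xb[:, k], y, subjects)
                p_dec = float(p_dec_all[k])
                rows.append(
                    (b, k, p_enc, p_dec, classify_channel(p_enc, p_dec, alpha, margin))
                )
        else:
            for k in range(binned.n_channels):
                rows.append((b, k, np.nan, np.nan, "undetermined"))
    return pd.DataFrame(rows, columns=["bin", "channel", "p_enc", "p_dec", "label"])
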