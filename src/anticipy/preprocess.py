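"""Preprocessing: artifact correction, filtering, baseline, binning.

Turns raw per-trial channel x sample traces into the trials x channels x
time-bins matrix consumed by the group statistics.  The chain follows
standard MEG practice for this kind of design: step-artifact (SQUID
reset) correction on the signal derivative, absolute-amplitude
screening, first-order Butterworth low-pass, baseline correction,
integer-stride down-sampling, and averaging into non-overlapping 10 ms
time bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "TrialEpochs",
    "BinnedDataset",
    "VALID_FLAGS",
    "correct_squid_jumps",
    "correct_epochs_jumps",
    "screen_amplitude",
    "filter_baseline_downsample",
    "bin_time",
    "apply_exclusions",
    "save_epochs",
    "load_epochs",
]

VALID_FLAGS = frozenset(
    {"jump_artifact", "amplitude_artifact", "incorrect_response", "misdetected_marker"}
)


@dataclass
class TrialEpochs:
    """Per-trial multichannel traces with subject and exclusion metadata.

    data : (trials, channels, samples), signal units (fT-like)
    epoch_window : (start_ms, end_ms) relative to cue onset
    """

    data: np.ndarray
    sample_rate: float
    epoch_window: tuple[float, float]
    subject: np.ndarray
    exclusion_flags: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        start, end = self.epoch_window
        expected = (end - start) / 1000.0 * self.sample_rate
        if abs(expected - self.data.shape[2]) > 1e-6:
            raise ValueError(
                f"sample count {self.data.shape[2]} inconsistent with window "
                f"{self.epoch_window} at {self.sample_rate} Hz (expected {expected:g})"
            )
        self.subject = np.asarray(self.subject)
        if len(self.subject) != self.n_trials:
            raise ValueError("subject labels must match trial count")
        if not self.exclusion_flags:
            self.exclusion_flags = [set() for _ in range(self.n_trials)]
        for fl in self.exclusion_flags:
            bad = set(fl) - VALID_FLAGS
            if bad:
                raise ValueError(f"unknown exclusion flags {bad}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        return self.epoch_window[0] + np.arange(self.n_samples) * 1000.0 / self.sample_rate


@dataclass
class BinnedDataset:
    """Trials x channels x time-bins array after bin averaging."""

    data: np.ndarray
    bin_width_ms: float
    bin_centers_ms: np.ndarray
    subject: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]


def correct_squid_jumps(
    trace: np.ndarray,
    jump_threshold: float = 3000.0,
    median_window: int = 21,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove step artifacts from one channel trace via its derivative.

    A jump is a first difference whose magnitude strictly exceeds
    ``jump_threshold``.  When jumps are present the difference series is
    median-filtered (length ``median_window``, reflect padding) and the
    trace rebuilt as the cumulative sum anchored at the first sample;
    a trace without jumps is returned unchanged, which makes the
    correction idempotent.

    Returns ``(corrected, jump_positions)`` where positions index the
    sample after which the offending difference occurs.
    """
    trace = np.asarray(trace, float)
    if jump_threshold <= 0:
        raise ValueError("jump_threshold must be positive")
    if median_window >= trace.size:
        raise ValueError("median_window must be smaller than the trace length")
    diff = np.diff(trace)
    jumps = np.flatnonzero(np.abs(diff) > jump_threshold)
    if jumps.size == 0:
        return trace.copy(), jumps
    filtered = ndimage.median_filter(diff, size=median_window, mode="reflect")
    corrected = np.empty_like(trace)
    corrected[0] = trace[0]
    corrected[1:] = trace[0] + np.cumsum(filtered)
    return corrected, jumps


def correct_epochs_jumps(
    epochs: TrialEpochs,
    jump_threshold: float = 3000.0,
    median_window: int = 21,
) -> tuple[TrialEpochs, dict]:
    """Apply jump correction per trial and channel; flag affected trials."""
    data = epochs.data.copy()
    flags = [set(fl) for fl in epochs.exclusion_flags]
    n_jumpy = 0
    for i in range(epochs.n_trials):
        hit = False
        for c in range(epochs.n_channels):
            data[i, c], jumps = correct_squid_jumps(
                data[i, c], jump_threshold, median_window
            )
            hit = hit or jumps.size > 0
        if hit:
            flags[i].add("jump_artifact")
            n_jumpy += 1
    out = replace(epochs, data=data, exclusion_flags=flags)
    return out, {"trials_with_jumps": n_jumpy, "n_trials": epochs.n_trials}


def screen_amplitude(
    epochs: TrialEpochs, abs_threshold: float = 3000.0
) -> tuple[TrialEpochs, dict]:
    """Flag trials containing any sample with |value| > abs_threshold."""
    if abs_threshold <= 0:
        raise ValueError("abs_threshold must be positive")
    bad = np.abs(epochs.data).max(axis=(1, 2)) > abs_threshold
    flags = [set(fl) for fl in epochs.exclusion_flags]
    for i in np.flatnonzero(bad):
        flags[i].add("amplitude_artifact")
    summary = {"flagged": int(bad.sum()), "n_trials": epochs.n_trials}
    return replace(epochs, exclusion_flags=flags), summary


def filter_baseline_downsample(
    epochs: TrialEpochs,
    cutoff: float = 80.0,
    baseline_window: tuple[float, float] | None = (-300.0, 0.0),
    target_rate: float = 200.0,
    zero_phase: bool = False,
) -> TrialEpochs:
    """Low-pass filter, baseline-correct, then decimate.

    First-order Butterworth low-pass, applied as a single forward pass by
    default (``zero_phase=True`` switches to filtfilt).  The per-trial,
    per-channel mean over ``baseline_window`` (half-open [t0, t1), ms) is
    subtracted; pass ``None`` to skip baseline correction.  Down-sampling
    keeps every k-th sample where k = sample_rate / target_rate must be an
    integer (the low-pass doubles as the anti-alias filter).
    """
    fs = epochs.sample_rate
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    factor = fs / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"target_rate {target_rate} does not divide sample_rate {fs}"
        )
    factor = int(round(factor))

    b, a = signal.butter(1, cutoff, btype="low", fs=fs)
    if zero_phase:
        data = signal.filtfilt(b, a, epochs.data, axis=2)
    else:
        data = signal.lfilter(b, a, epochs.data, axis=2)

    if baseline_window is not None:
        t = epochs.times_ms()
        lo, hi = baseline_window
        if lo < epochs.epoch_window[0] or hi > epochs.epoch_window[1]:
            raise ValueError("baseline window outside the epoch")
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            raise ValueError("baseline window contains no samples")
        data = data - data[:, :, mask].mean(axis=2, keepdims=True)

    data = data[:, :, ::factor]
    return replace(epochs, data=data, sample_rate=target_rate)


def bin_time(
    epochs: TrialEpochs,
    bin_width_ms: float = 10.0,
    analysis_window: tuple[float, float] | None = None,
) -> BinnedDataset:
    """Average samples into consecutive non-overlapping time bins.

    Bins are left-closed, right-open intervals [t, t + width); the bin
    center is reported as t + width/2.  The window length must be an
    integer multiple of the bin width and each bin must hold an integer
    number of samples.
    """
    if analysis_window is None:
        analysis_window = epochs.epoch_window
    lo, hi = analysis_window
    length = hi - lo
    n_bins = length / bin_width_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(
            f"bin width {bin_width_ms} ms does not divide window length {length} ms "
            f"(remainder {length % bin_width_ms:g} ms)"
        )
    n_bins = int(round(n_bins))
    spb = bin_width_ms * epochs.sample_rate / 1000.0
    if abs(spb - round(spb)) > 1e-9:
        raise ValueError("bin width must hold an integer number of samples")
    spb = int(round(spb))
    t = epochs.times_ms()
    mask = (t >= lo) & (t < hi)
    n_keep = int(mask.sum())
    if n_keep != n_bins * spb:
        raise ValueError(
            f"window holds {n_keep} samples, expected {n_bins * spb} "
            f"({n_bins} bins x {spb} samples)"
        )
    sel = epochs.data[:, :, mask]
    binned = sel.reshape(sel.shape[0], sel.shape[1], n_bins, spb).mean(axis=3)
    centers = lo + (np.arange(n_bins) + 0.5) * bin_width_ms
    return BinnedDataset(
        data=binned,
        bin_width_ms=bin_width_ms,
        bin_centers_ms=centers,
        subject=epochs.subject.copy(),
    )


def apply_exclusions(epochs: TrialEpochs) -> tuple[TrialEpochs, dict]:
    """Drop flagged trials; report per-reason percentages of the original count.

    A trial flagged for several reasons is removed once but counted under
    every reason it carries.
    """
    n = epochs.n_trials
    keep = np.array([len(fl) == 0 for fl in epochs.exclusion_flags])
    if not keep.any():
        raise ValueError("all trials excluded")
    reasons = {r: 0 for r in sorted(VALID_FLAGS)}
    for fl in epochs.exclusion_flags:
        for r in fl:
            reasons[r] += 1
    report = {
        "n_trials": n,
        "n_kept": int(keep.sum()),
        "kept_indices": np.flatnonzero(keep),
        "percent_by_reason": {r: 100.0 * c / n for r, c in reasons.items()},
    }
    out = TrialEpochs(
        data=epochs.data[keep],
        sample_rate=epochs.sample_rate,
        epoch_window=epochs.epoch_window,
        subject=epochs.subject[keep],
        exclusion_flags=[set() for _ in range(int(keep.sum()))],
    )
    return out, report


def save_epochs(path, epochs: TrialEpochs, seed: int | None = None) -> None:
    """Write epochs to a portable .npz container (flags as a string array)."""
    flags = np.array(
        ["|".join(sorted(fl)) for fl in epochs.exclusion_flags], dtype=object
    )
    np.savez_compressed(
        path,
        data=epochs.data,
        sample_rate=epochs.sample_rate,
        epoch_window=np.asarray(epochs.epoch_window, float),
        subject=epochs.subject,
        flags=flags.astype(str),
        seed=-1 if seed is None else seed,
    )


def load_epochs(path) -> TrialEpochs:
    with np.load(path, allow_pickle=False) as z:
        flags = [set(s.split("|")) - {""} for s in z["flags"]]
        return TrialEpochs(
            data=z["data"],
            sample_rate=float(z["sample_rate"]),
            epoch_window=tuple(z["epoch_window"]),
            subject=z["subject"],
            exclusion_flags=flags,
        )
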