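"""Synthetic multi-subject trial data with planted ground truth.

Emulates a reward-anticipation study in which geometric cues signal a
3 x 3 factorial of expected mean reward (default 1, 2, 3 pounds) and
reward variability (coefficient of variation 0.08, 0.16, 0.24).  The
perceptual cue features (fill, color) are perfectly confounded with the
reward features within any single subject, but the cue-feature-to-reward
mapping is counterbalanced across subjects so that, pooled over a
balanced group, perceptual and reward features are exactly orthogonal.

Channels carry one of four roles with respect to a stimulus feature:

direct
    responds linearly to the feature value with a time course that ramps
    up after an onset latency; the multichannel response pattern may
    drift (rotate) over the epoch and optionally freeze after the epoch
    midpoint to emulate stabilising representations.
indirect
    an affine copy of a direct channel plus private noise; its relation
    to the feature is entirely mediated by that direct channel.
context
    loads on the shared "brain state" noise component that also drives
    direct channels, but has zero marginal dependence on the feature.
null
    pure noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import TrialEpochs

__all__ = [
    "DesignSpec",
    "ChannelEffect",
    "GroundTruth",
    "balanced_counterbalance",
    "generate_dataset",
    "generate_reward_outcomes",
    "generate_certainty_equivalents",
    "inject_jump",
]

FEATURES = ("mean", "variability", "fill", "color")


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of the emulated study.

    Defaults reproduce the source-level configuration: 18 subjects,
    450 trials each, 13 channels, 200 Hz sampling over the 0-2000 ms
    anticipation window.
    """

    n_subjects: int = 18
    n_trials_per_subject: int = 450
    n_channels: int = 13
    sample_rate: float = 200.0
    epoch_window: tuple[float, float] = (0.0, 2000.0)
    mean_levels: tuple[float, ...] = (1.0, 2.0, 3.0)
    cv_levels: tuple[float, ...] = (0.08, 0.16, 0.24)
    p_incorrect: float = 0.029
    counterbalance: tuple[tuple[bool, bool, bool], ...] | None = None

    def __post_init__(self):
        if len(self.mean_levels) < 2 or len(self.cv_levels) < 2:
            raise ValueError("mean_levels and cv_levels each need >= 2 entries")
        n_cells = len(self.mean_levels) * len(self.cv_levels)
        if self.n_trials_per_subject % n_cells:
            raise ValueError(
                f"n_trials_per_subject must be a multiple of {n_cells} "
                f"(one factorial repetition), got {self.n_trials_per_subject}"
            )

    @property
    def n_samples(self) -> int:
        start, end = self.epoch_window
        n = (end - start) / 1000.0 * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch window must hold an integer number of samples")
        return int(round(n))

    def times_ms(self) -> np.ndarray:
        start = self.epoch_window[0]
        return start + np.arange(self.n_samples) * 1000.0 / self.sample_rate

    def resolved_counterbalance(self) -> tuple[tuple[bool, bool, bool], ...]:
        if self.counterbalance is not None:
            if len(self.counterbalance) != self.n_subjects:
                raise ValueError("counterbalance table length != n_subjects")
            return self.counterbalance
        return balanced_counterbalance(self.n_subjects)


def balanced_counterbalance(n_subjects: int) -> tuple[tuple[bool, bool, bool], ...]:
    """Assignment table (fill_reversed, color_reversed, hand_swapped) per subject.

    Half of the subjects get the reversed fill-to-mean mapping and half the
    reversed color-to-variability mapping, so the pooled group correlation
    between perceptual and reward features is exactly zero.
    """
    if n_subjects % 2:
        valid = ", ".join(str(k) for k in range(2, n_subjects + 3, 2))
        raise ValueError(
            f"counterbalancing requires an even subject count; {n_subjects} is odd "
            f"(valid nearby counts: {valid})"
        )
    table = []
    for s in range(n_subjects):
        fill_rev = s >= n_subjects // 2
        color_rev = s % 2 == 1
        hand_swap = (s // 2) % 2 == 1
        table.append((fill_rev, color_rev, hand_swap))
    return tuple(table)


@dataclass(frozen=True)
class ChannelEffect:
    """Role of one channel with respect to one stimulus feature."""

    channel: int
    feature: str  # one of FEATURES
    role: str  # direct | indirect | context
    amplitude: float = 1.0  # direct: signal units per (centred) feature unit
    source: int | None = None  # indirect/context: the mediating direct channel
    gain: float = 1.0  # indirect: multiplier on source; context: state loading


@dataclass(frozen=True)
class GroundTruth:
    """Planted effect structure for :func:`generate_dataset`."""

    effects: tuple[ChannelEffect, ...] = ()
    onset_ms: dict = field(
        default_factory=lambda: {
            "fill": 110.0,
            "color": 130.0,
            "mean": 250.0,
            "variability": 540.0,
        }
    )
    rise_ms: float = 100.0
    noise_sd: float = 1.0
    shared_noise_sd: float = 1.0
    state_tau_ms: float = 50.0  # correlation time of the brain-state process
    subject_pattern_sd: float = 0.0
    drift: bool = False
    stabilize: bool = True  # freeze the pattern over the second epoch half

    def validate(self, spec: DesignSpec) -> None:
        direct = {
            (e.channel, e.feature) for e in self.effects if e.role == "direct"
        }
        direct_channels = {c for c, _ in direct}
        for e in self.effects:
            if e.feature not in FEATURES:
                raise ValueError(f"unknown feature {e.feature!r}")
            if e.role not in ("direct", "indirect", "context"):
                raise ValueError(f"unknown role {e.role!r}")
            if not 0 <= e.channel < spec.n_channels:
                raise ValueError(f"channel {e.channel} outside 0..{spec.n_channels - 1}")
            if e.role in ("indirect", "context"):
                if e.source is None or e.source not in direct_channels:
                    raise ValueError(
                        f"{e.role} channel {e.channel} references source {e.source}, "
                        "which is not a direct channel"
                    )


def _ramp(t_ms: np.ndarray, onset: float, rise: float) -> np.ndarray:
    """0 before onset, linear rise over `rise` ms, then 1."""
    if rise <= 0:
        return (t_ms >= onset).astype(float)
    return np.clip((t_ms - onset) / rise, 0.0, 1.0)


def _slerp(u0: np.ndarray, u1: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors; shape (len(s), dim)."""
    dot = float(np.clip(u0 @ u1, -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-12:
        return np.tile(u0, (len(s), 1))
    so = math.sin(omega)
    a = np.sin((1.0 - s) * omega) / so
    b = np.sin(s * omega) / so
    return a[:, None] * u0[None, :] + b[:, None] * u1[None, :]


def _subject_design(spec: DesignSpec, subject: int, rng: np.random.Generator) -> pd.DataFrame:
    """Trial table for one subject honouring the counterbalance map."""
    fill_rev, color_rev, hand_swap = spec.resolved_counterbalance()[subject]
    n_mean, n_cv = len(spec.mean_levels), len(spec.cv_levels)
    reps = spec.n_trials_per_subject // (n_mean * n_cv)
    mi, vi = np.meshgrid(np.arange(n_mean), np.arange(n_cv), indexing="ij")
    mi = np.tile(mi.ravel(), reps)
    vi = np.tile(vi.ravel(), reps)
    order = rng.permutation(len(mi))
    mi, vi = mi[order], vi[order]
    fill = (n_mean - 1) - mi if fill_rev else mi
    color = (n_cv - 1) - vi if color_rev else vi
    return pd.DataFrame(
        {
            "subject": subject,
            "mean_reward": np.asarray(spec.mean_levels)[mi],
            "cv": np.asarray(spec.cv_levels)[vi],
            "fill": fill,
            "color": color,
            "hand_swapped": hand_swap,
        }
    )


def generate_dataset(
    spec: DesignSpec,
    truth: GroundTruth,
    seed: int,
) -> tuple[TrialEpochs, pd.DataFrame, GroundTruth]:
    """Simulate trial epochs plus the per-trial stimulus table.

    Returns ``(epochs, stimulus_table, truth)``.  ``epochs.data`` has shape
    (trials, channels, samples); the stimulus table holds per-trial subject,
    trial index, feature values and response correctness.  Deterministic
    given ``seed``.
    """
    truth.validate(spec)
    rng = np.random.default_rng(seed)
    t_ms = spec.times_ms()
    n_sub, n_tr, n_ch, n_sam = (
        spec.n_subjects,
        spec.n_trials_per_subject,
        spec.n_channels,
        spec.n_samples,
    )

    tables = [_subject_design(spec, s, rng) for s in range(n_sub)]
    stim = pd.concat(tables, ignore_index=True)
    stim.insert(1, "trial", np.tile(np.arange(n_tr), n_sub))
    stim["correct"] = rng.random(len(stim)) >= spec.p_incorrect

    n_total = len(stim)
    data = rng.normal(0.0, truth.noise_sd, size=(n_total, n_ch, n_sam))

    # Shared brain-state component: a slow stochastic process per trial
    # (smoothed white noise with correlation time state_tau_ms), gated on at
    # cue onset so a pre-cue baseline window stays clean.  A process rather
    # than a per-trial constant: chance correlations with the stimulus then
    # decorrelate across time bins instead of contaminating every bin
    # coherently.
    state = rng.normal(size=(n_total, n_sam))
    if truth.state_tau_ms > 0 and n_sam > 1:
        sigma = truth.state_tau_ms / 1000.0 * spec.sample_rate
        state = ndimage.gaussian_filter1d(state, sigma, axis=1, mode="reflect")
        state /= state.std() or 1.0
    state *= truth.shared_noise_sd
    state_gate = _ramp(t_ms, 0.0, truth.rise_ms)
    state *= state_gate[None, :]

    feature_values = {
        "mean": stim["mean_reward"].to_numpy(float),
        "variability": stim["cv"].to_numpy(float),
        "fill": stim["fill"].to_numpy(float),
        "color": stim["color"].to_numpy(float),
    }
    subj_idx = stim["subject"].to_numpy()

    direct = [e for e in truth.effects if e.role == "direct"]
    direct_channels = sorted({e.channel for e in direct})
    for c in direct_channels:
        data[:, c, :] += state

    # Direct effects: per feature, a (possibly drifting) pattern over that
    # feature's direct channels, scaled by the onset-latency ramp.
    for feat in FEATURES:
        effs = [e for e in direct if e.feature == feat]
        if not effs:
            continue
        onset = truth.onset_ms.get(feat, 0.0)
        beta_t = _ramp(t_ms, onset, truth.rise_ms)
        z = feature_values[feat]
        z = z - z.mean()
        dim = len(effs)
        if truth.drift and dim > 1:
            u0 = rng.normal(size=dim)
            u0 /= np.linalg.norm(u0)
            u1 = rng.normal(size=dim)
            u1 -= (u1 @ u0) * u0
            u1 /= np.linalg.norm(u1)
            t_end = t_ms[-1] if t_ms[-1] > 0 else 1.0
            frac = np.clip(t_ms / t_end, 0.0, 1.0)
            if truth.stabilize:
                frac = np.minimum(frac, 0.5) * 2.0
            pattern = _slerp(u0, u1, frac) * math.sqrt(dim)  # (samples, dim)
        else:
            pattern = np.ones((n_sam, dim))
        pert = rng.normal(0.0, truth.subject_pattern_sd, size=(n_sub, dim))
        for j, e in enumerate(effs):
            w = e.amplitude * (pattern[:, j][None, :] + pert[subj_idx, j][:, None])
            data[:, e.channel, :] += w * (beta_t[None, :] * z[:, None])

    for e in truth.effects:
        if e.role == "indirect":
            data[:, e.channel, :] += e.gain * data[:, e.source, :]
        elif e.role == "context":
            data[:, e.channel, :] += e.gain * state

    flags = [set() if ok else {"incorrect_response"} for ok in stim["correct"]]
    epochs = TrialEpochs(
        data=data,
        sample_rate=spec.sample_rate,
        epoch_window=spec.epoch_window,
        subject=subj_idx.copy(),
        exclusion_flags=flags,
    )
    return epochs, stim, truth


def generate_reward_outcomes(
    mean: float, cv: float, n_outcomes: int = 3, seed: int | None = None
) -> np.ndarray:
    """Discrete outcome set with exact sample mean and coefficient of variation.

    The default symmetric 3-point construction is {mean - d, mean, mean + d}
    with d = cv * mean * sqrt(3/2); under uniform probability its mean is
    `mean` and its CV is exactly `cv`.  For n_outcomes > 3 the set is built
    from symmetric equally spaced points rescaled to the requested CV.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if n_outcomes < 2:
        raise ValueError("need at least 2 outcomes")
    if n_outcomes == 3 or cv == 0:
        if cv == 0:
            return np.full(n_outcomes, float(mean))
        delta = cv * mean * math.sqrt(1.5)
        out = np.array([mean - delta, mean, mean + delta])
    else:
        grid = np.linspace(-1.0, 1.0, n_outcomes)
        grid *= cv * mean / grid.std()
        out = mean + grid
    if np.any(out <= 0):
        raise ValueError(
            f"outcome construction yields a non-positive value "
            f"(min {out.min():.4g}); requires cv*sqrt(3/2) < 1"
        )
    return out


def _exp_utility(c, a):
    c = np.asarray(c, float)
    if abs(a) <= 1e-8:
        return c
    return -np.expm1(-c * a) / a


def _invert_utility(eu: float, a: float) -> float:
    if abs(a) <= 1e-8:
        return float(eu)
    if a * eu >= 1.0:
        raise OverflowError("expected utility outside the range of u for this a")
    return float(-math.log1p(-a * eu) / a)


def generate_certainty_equivalents(
    true_a,
    spec: DesignSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated certainty-equivalent bids for every cue and subject.

    ``true_a`` is a scalar risk-sensitivity parameter or one value per
    subject.  The noiseless certainty equivalent c* of a cue solves
    u(c*) = E[u(outcome)] under exponential utility with parameter a;
    Gaussian elicitation noise of SD ``noise_sd`` is then added.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    a_vec = np.broadcast_to(np.asarray(true_a, float), (spec.n_subjects,))
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(spec.n_subjects):
        a = float(a_vec[s])
        cue = 0
        for m in spec.mean_levels:
            for cv in spec.cv_levels:
                outcomes = generate_reward_outcomes(m, cv)
                eu = float(np.mean(_exp_utility(outcomes, a)))
                c_star = _invert_utility(eu, a)
                ce = c_star + rng.normal(0.0, noise_sd) if noise_sd else c_star
                rows.append(
                    {
                        "subject": s,
                        "cue": cue,
                        "mean_reward": m,
                        "cv": cv,
                        "certainty_equivalent": ce,
                    }
                )
                cue += 1
    return pd.DataFrame(rows)


def inject_jump(trace: np.ndarray, position: int, step: float) -> np.ndarray:
    """Add a sensor-reset-like step artifact to a copy of `trace`."""
    out = np.asarray(trace, float).copy()
    out[position:] += step
    return out
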