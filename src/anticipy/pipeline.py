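"""End-to-end orchestration with a single reproducible run descriptor.

A :class:`RunConfig` captures every stage parameter and seed; the run
directory receives plain CSV/JSON artifacts (epochs as an .npz array
container) so that two runs with identical configs produce identical
numeric outputs.  Every CSV starts with a comment line carrying the
config hash; JSON artifacts embed it as a field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crosspred, inference, metrics, preprocess, simulate, utility
from .preprocess import BinnedDataset

__all__ = ["RunConfig", "run_pipeline", "default_truth"]

log = logging.getLogger("anticipy")


@dataclass
class RunConfig:
    # design (demo scale; the full study design is DesignSpec's defaults)
    n_subjects: int = 12
    n_trials_per_subject: int = 90
    n_channels: int = 20
    sample_rate: float = 200.0
    epoch_window: tuple = (0.0, 1000.0)
    seed: int = 0
    # preprocessing
    jump_threshold: float = 3000.0
    median_window: int = 21
    amplitude_threshold: float = 3000.0
    lowpass_hz: float = 80.0
    baseline_window: tuple | None = None
    target_rate: float = 200.0
    bin_width_ms: float = 10.0
    # statistics
    features: tuple = ("mean", "variability", "fill", "color")
    n_perm_cluster: int = 500
    n_perm_trial: int = 500
    n_perm_time: int = 5000
    cluster_alpha: float = 0.05
    alpha: float = 0.05
    split_ms: float = 500.0
    # simulator effect structure
    effect_amplitude: float = 0.6
    noise_sd: float = 1.0
    shared_noise_sd: float = 1.0
    drift: bool = True
    stabilize: bool = True
    # utility stage: population mean/SD of risk sensitivity, elicitation noise
    true_risk_a: float = 0.13
    risk_a_sd: float = 0.26
    ce_noise_sd: float = 0.05
    # stage toggles
    stages: tuple = (
        "simulate",
        "preprocess",
        "fit",
        "classify",
        "xpred",
        "metrics",
        "utility",
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("epoch_window", "features", "stages", "baseline_window"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for key in ("epoch_window", "features", "stages", "baseline_window"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def default_truth(cfg: RunConfig) -> simulate.GroundTruth:
    """Planted structure for the demo pipeline.

    Channels 0-1 directly encode mean reward, 2-3 variability, 4 fill and
    5 color; 6 is an indirect copy of channel 0; 7 is a brain-state
    context channel; the remainder are null.  Onsets are scaled into the
    configured window.
    """
    span = cfg.epoch_window[1] - cfg.epoch_window[0]
    scale = span / 2000.0
    a = cfg.effect_amplitude
    effects = (
        simulate.ChannelEffect(0, "mean", "direct", amplitude=a),
        simulate.ChannelEffect(1, "mean", "direct", amplitude=a),
        simulate.ChannelEffect(2, "variability", "direct", amplitude=8 * a),
        simulate.ChannelEffect(3, "variability", "direct", amplitude=8 * a),
        simulate.ChannelEffect(4, "fill", "direct", amplitude=a),
        simulate.ChannelEffect(5, "color", "direct", amplitude=a),
        simulate.ChannelEffect(6, "mean", "indirect", source=0, gain=0.8),
        simulate.ChannelEffect(7, "mean", "context", source=0, gain=1.0),
    )
    onsets = {
        "fill": 110.0 * scale,
        "color": 130.0 * scale,
        "mean": 250.0 * scale,
        "variability": 540.0 * scale,
    }
    return simulate.GroundTruth(
        effects=effects,
        onset_ms=onsets,
        rise_ms=100.0 * scale,
        noise_sd=cfg.noise_sd,
        shared_noise_sd=cfg.shared_noise_sd,
        drift=cfg.drift,
        stabilize=cfg.stabilize,
    )


def _feature_vector(stim: pd.DataFrame, feature: str) -> np.ndarray:
    col = {"mean": "mean_reward", "variability": "cv", "fill": "fill", "color": "color"}
    return stim[col[feature]].to_numpy(float)


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def _write_json(obj: dict, path: Path, cfg_hash: str) -> None:
    obj = {"config_hash": cfg_hash, **obj}
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Execute the toggled stages, writing artifacts into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = cfg.hash()
    cfg.to_yaml(outdir / "config.yaml")
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("run start, config hash %s", h)

    spec = simulate.DesignSpec(
        n_subjects=cfg.n_subjects,
        n_trials_per_subject=cfg.n_trials_per_subject,
        n_channels=cfg.n_channels,
        sample_rate=cfg.sample_rate,
        epoch_window=cfg.epoch_window,
    )
    truth = default_truth(cfg)
    stages = set(cfg.stages)
    epochs = stim = binned = None
    cluster_by_feature = {}

    try:
        if "simulate" in stages:
            epochs, stim, _ = simulate.generate_dataset(spec, truth, cfg.seed)
            preprocess.save_epochs(outdir / "epochs.npz", epochs, seed=cfg.seed)
            _write_csv(stim, outdir / "trials.csv", h)
            log.info("simulate: %d trials x %d channels x %d samples",
                     epochs.n_trials, epochs.n_channels, epochs.n_samples)

        if "preprocess" in stages:
            epochs, jump_report = preprocess.correct_epochs_jumps(
                epochs, cfg.jump_threshold, cfg.median_window
            )
            epochs, amp_report = preprocess.screen_amplitude(
                epochs, cfg.amplitude_threshold
            )
            if cfg.sample_rate != cfg.target_rate or cfg.baseline_window is not None:
                epochs = preprocess.filter_baseline_downsample(
                    epochs, cfg.lowpass_hz, cfg.baseline_window, cfg.target_rate
                )
            epochs, excl_report = preprocess.apply_exclusions(epochs)
            stim = stim.iloc[excl_report["kept_indices"]].reset_index(drop=True)
            binned = preprocess.bin_time(epochs, cfg.bin_width_ms)
            _write_json(
                {
                    "jumps": jump_report,
                    "amplitude": amp_report,
                    "exclusions": {
                        k: v for k, v in excl_report.items() if k != "kept_indices"
                    },
                    "n_bins": binned.n_bins,
                },
                outdir / "preprocess_report.json",
                h,
            )
            log.info("preprocess: kept %d/%d trials, %d bins",
                     excl_report["n_kept"], excl_report["n_trials"], binned.n_bins)

        if "fit" in stages or "classify" in stages:
            from .models import fit_decoding, fit_encoding

            for feat in cfg.features:
                y = _feature_vector(stim, feat)
                rows = []
                for b in range(binned.n_bins):
                    Xb = binned.data[:, :, b]
                    enc = fit_encoding(Xb, y, binned.subject)
                    dec = fit_decoding(Xb, y, binned.subject)
                    rows.append(
                        {
                            "bin_center_ms": binned.bin_centers_ms[b],
                            "pillai": enc.pillai,
                            "F_enc": enc.F,
                            "df1_enc": enc.df1,
                            "df2_enc": enc.df2,
                            "p_enc": enc.p,
                            "F_dec": dec.F,
                            "p_dec": dec.p,
                            "r2_dec": dec.r2,
                        }
                    )
                _write_csv(pd.DataFrame(rows), outdir / f"trace_{feat}.csv", h)
                log.info("fit: feature %s done", feat)

        if "classify" in stages:
            for feat in cfg.features:
                y = _feature_vector(stim, feat)
                cres = inference.cluster_permutation(
                    binned,
                    y,
                    n_perm=cfg.n_perm_cluster,
                    cluster_alpha=cfg.cluster_alpha,
                    alpha=cfg.alpha,
                    seed=cfg.seed + 1,
                )
                cluster_by_feature[feat] = cres
                labels = inference.classify_all(binned, y, cluster=cres)
                labels.insert(0, "feature", feat)
                _write_csv(labels, outdir / f"labels_{feat}.csv", h)
                ct = pd.DataFrame(
                    cres.clusters, columns=["start_bin", "end_bin", "mass", "p"]
                )
                _write_csv(ct, outdir / f"clusters_{feat}.csv", h)
                log.info("classify: %s, %d cluster(s)", feat, len(cres.clusters))

        if "xpred" in stages:
            y = _feature_vector(stim, "mean")
            xpm = crosspred.cross_predict(
                binned, y, seed=cfg.seed + 2, n_perm_trial=cfg.n_perm_trial
            )
            stab = crosspred.stability_statistic(
                xpm, cfg.split_ms, max(cfg.n_perm_time, 1000), seed=cfg.seed + 3
            )
            xpm_n = crosspred.normalize_by_source_fit(xpm)
            stab_n = crosspred.stability_statistic(
                xpm_n, cfg.split_ms, max(cfg.n_perm_time, 1000), seed=cfg.seed + 3
            )
            _write_csv(
                pd.DataFrame(xpm.ev_thresholded), outdir / "xpred_matrix.csv", h
            )
            _write_json(
                {
                    "statistic": stab.statistic,
                    "p": stab.p,
                    "diag_statistic": stab.diag_statistic,
                    "diag_p": stab.diag_p,
                    "normalized_statistic": stab_n.statistic,
                    "normalized_p": stab_n.p,
                    "split_ms": cfg.split_ms,
                    "n_perm_trial": cfg.n_perm_trial,
                    "n_perm_time": cfg.n_perm_time,
                    "seed": cfg.seed,
                },
                outdir / "stability.json",
                h,
            )
            log.info("xpred: stability stat %.4f (p=%.4g)", stab.statistic, stab.p)

        if "metrics" in stages:
            ev = metrics.compare_variability_metrics(binned, stim, scope="pooled")
            per_chan = metrics.compare_variability_metrics(
                binned, stim, scope="per-channel"
            )
            pref = metrics.preferential_encoding(binned, stim)
            table = per_chan.merge(pref[["channel", "preference", "delta_aic"]], on="channel")
            _write_csv(table, outdir / "metric_table.csv", h)
            _write_json(
                {"summed_aic": ev.aic, "winner": ev.winner},
                outdir / "metric_comparison.json",
                h,
            )
            log.info("metrics: pooled winner %s", ev.winner)

        if "utility" in stages:
            rng = np.random.default_rng(cfg.seed + 5)
            a_pop = rng.normal(cfg.true_risk_a, cfg.risk_a_sd, size=cfg.n_subjects)
            ce = simulate.generate_certainty_equivalents(
                a_pop, spec, cfg.ce_noise_sd, seed=cfg.seed + 4
            )
            outcome_sets = {
                int(c): simulate.generate_reward_outcomes(m, v)
                for c, m, v in ce[["cue", "mean_reward", "cv"]]
                .drop_duplicates()
                .itertuples(index=False)
            }
            fit = utility.fit_risk_sensitivity(ce, outcome_sets)
            _write_csv(fit.per_subject, outdir / "utility_subjects.csv", h)
            _write_json(
                {
                    "group_mean_a": fit.group_mean_a,
                    "group_sd_a": fit.group_sd_a,
                    "t_stat": fit.t_stat,
                    "t_p": fit.t_p,
                    "delta_aic_vs_expected_value": fit.delta_aic,
                },
                outdir / "utility.json",
                h,
            )
            log.info("utility: mean a=%.4f", fit.group_mean_a)
    except Exception as exc:  # pragma: no cover - re-raised with stage context
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
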