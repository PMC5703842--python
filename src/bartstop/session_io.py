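"""Session container formats, pipeline configuration, and the top-level runner.

A session directory holds ``trials.csv`` (the trial table), ``spikes.csv``
(``unit_id, timestamp_s``), ``lfp.h5`` (``lfp`` dataset, channels x samples,
with ``fs_hz`` and channel-name attributes, optionally an ``artifact_mask``
dataset), and ``config.json`` (generator parameters and seeds). Times are
seconds (floats) on a single session clock; intervals are half-open.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from bartstop import behavior, cluster_stats, hazard_model, lfp_processing, spike_model
from bartstop.containers import (
    TRIAL_COLUMNS,
    LfpRecording,
    SpikeData,
    validate_trials,
)
from bartstop.seeds import derive_seed


class SchemaError(ValueError):
    """A session file is missing or violates the expected schema."""


@dataclass
class SessionBundle:
    trials: pd.DataFrame
    spikes: SpikeData
    lfp: LfpRecording
    config: dict


def write_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write a session directory; round-trips bit-exactly for table values."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    validate_trials(bundle.trials)
    bundle.trials.to_csv(path / "trials.csv", index=False)
    rows = [
        {"unit_id": u, "timestamp_s": t}
        for u, ts in bundle.spikes.timestamps.items()
        for t in ts
    ]
    pd.DataFrame(rows, columns=["unit_id", "timestamp_s"]).to_csv(
        path / "spikes.csv", index=False
    )
    with h5py.File(path / "lfp.h5", "w") as f:
        d = f.create_dataset("lfp", data=bundle.lfp.data)
        d.attrs["fs_hz"] = bundle.lfp.fs_hz
        d.attrs["channel_ids"] = [c.encode() for c in bundle.lfp.channel_ids]
        if bundle.lfp.artifact_mask is not None:
            f.create_dataset("artifact_mask", data=bundle.lfp.artifact_mask)
    cfg = dict(bundle.config)
    cfg.setdefault("session_duration_s", bundle.spikes.session_duration_s)
    (path / "config.json").write_text(json.dumps(cfg, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_session(path: str | Path) -> SessionBundle:
    """Read and validate a session directory."""
    path = Path(path)
    for fname in ("trials.csv", "spikes.csv", "lfp.h5", "config.json"):
        if not (path / fname).exists():
            raise SchemaError(f"missing session file: {path / fname}")
    trials = pd.read_csv(path / "trials.csv")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trials.csv missing columns {missing}")
    validate_trials(trials)
    config = json.loads((path / "config.json").read_text())

    sp = pd.read_csv(path / "spikes.csv")
    for col in ("unit_id", "timestamp_s"):
        if col not in sp.columns:
            raise SchemaError(f"spikes.csv missing column {col!r}")
    with h5py.File(path / "lfp.h5", "r") as f:
        if "lfp" not in f:
            raise SchemaError("lfp.h5 missing 'lfp' dataset")
        d = f["lfp"]
        fs = float(d.attrs["fs_hz"])
        chans = [c.decode() if isinstance(c, bytes) else str(c) for c in d.attrs["channel_ids"]]
        data = d[()]
        mask = f["artifact_mask"][()] if "artifact_mask" in f else None
    if "fs_hz" in config and not np.isclose(float(config["fs_hz"]), fs):
        raise SchemaError(
            f"fs mismatch: config.json says {config['fs_hz']} Hz, lfp.h5 says {fs} Hz"
        )
    duration = float(
        config.get("session_duration_s", data.shape[1] / fs)
    )
    spikes = SpikeData(
        timestamps={
            str(u): np.sort(g["timestamp_s"].to_numpy(float))
            for u, g in sp.groupby("unit_id")
        },
        session_duration_s=duration,
    )
    lfp = LfpRecording(data=data, fs_hz=fs, channel_ids=chans, artifact_mask=mask)
    return SessionBundle(trials=trials, spikes=spikes, lfp=lfp, config=config)


@dataclass
class PipelineConfig:
    """All stage parameters plus the master seed; serializable and logged.

    Per-stage seeds are derived deterministically from ``master_seed`` and
    the stage name, so a full run is reproducible from one number.
    """

    master_seed: int = 0
    bin_s: float = 0.05
    glm_folds: int = 10
    glm_mixing_grid: tuple = (0.5,)
    glm_rule: str = "1SE"
    bands: tuple = ("theta", "beta")
    peri_window_s: tuple = (-2.0, 1.0)
    tfr_window_s: tuple = (-2.5, 1.5)
    tfr_baseline_s: tuple = (-1.5, -0.5)
    n_freqs: int = 30
    n_perm: int = 200
    hazard_fs_hz: float = 40.0
    hazard_window_s: float = 0.5
    mcmc_chains: int = 2
    mcmc_iters: int = 600
    mcmc_warmup: int = 300
    mcmc_thin: int = 3

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(bundle: SessionBundle, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every analysis stage on a session and write all outputs.

    Order: behavior summary -> spiking GLM -> LFP band power and traces ->
    time-frequency cluster statistics (banked vs popped stops) -> hazard
    model. Writes CSV outputs per stage plus ``run_log.json`` with
    parameters, derived seeds, durations, and captured warnings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": config.to_dict(), "stages": {}, "warnings": []}

    def _stage(name):
        t0 = time.perf_counter()

        def done(**info):
            log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}

        return done

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        done = _stage("behavior")
        summary = behavior.behavioral_summary(bundle.trials)
        summary.to_csv(out / "behavior_summary.csv", index=False)
        done(rows=len(summary))

        done = _stage("spike_model")
        seed = derive_seed(config.master_seed, "spike_model")
        filtered = spike_model.filter_units(bundle.spikes)
        design = spike_model.build_design(bundle.trials, bin_s=config.bin_s)
        effects = []
        for unit, ts in filtered.timestamps.items():
            counts = np.histogram(ts, bins=design.edges)[0]
            fit = spike_model.fit_poisson_glm(
                design,
                counts,
                folds=config.glm_folds,
                mixing_grid=config.glm_mixing_grid,
                rule=config.glm_rule,
                seed=seed,
            )
            eff = spike_model.effect_sizes(fit)
            eff.insert(0, "unit_id", unit)
            eff["baseline_rate_hz"] = fit.baseline_rate_hz
            effects.append(eff)
        eff_table = (
            pd.concat(effects, ignore_index=True) if effects else pd.DataFrame()
        )
        eff_table.to_csv(out / "spike_effects.csv", index=False)
        done(n_units=len(filtered.timestamps), seed=seed)

        done = _stage("lfp_processing")
        car = lfp_processing.common_average_reference(bundle.lfp)
        mask = lfp_processing.detect_artifacts(car)
        car = car.copy_with(artifact_mask=mask)
        free_banked = (bundle.trials["type"] == "free") & (
            bundle.trials["outcome"] == "banked"
        )
        stop_times = (
            bundle.trials.loc[free_banked, "t_start_s"]
            + bundle.trials.loc[free_banked, "t_stop_s"]
        ).to_numpy(float)
        popped = bundle.trials["outcome"] == "popped"
        pop_times = (
            bundle.trials.loc[popped, "t_start_s"]
            + bundle.trials.loc[popped, "t_pop_s"]
        ).to_numpy(float)
        band_powers = []
        trace_rows = []
        for band_name in config.bands:
            band = lfp_processing.CANONICAL_BANDS[band_name]
            series = lfp_processing.band_power(car, band)
            band_powers.extend(series)
            traces = [
                lfp_processing.peri_event_trace(s, stop_times, config.peri_window_s)
                for s in series
            ]
            avg = lfp_processing.average_traces(traces)
            trace_rows.append(
                pd.DataFrame(
                    {
                        "band": band_name,
                        "time_s": avg.times_s,
                        "z_log_power": avg.trace,
                        "n_events": avg.n_events,
                    }
                )
            )
        pd.concat(trace_rows, ignore_index=True).to_csv(
            out / "peri_stop_traces.csv", index=False
        )
        done(n_series=len(band_powers))

        done = _stage("cluster_stats")
        seed = derive_seed(config.master_seed, "cluster_stats")
        freqs = np.geomspace(2.5, 50.0, config.n_freqs)
        fs200 = lfp_processing.POWER_FS_HZ
        x200 = None
        cluster_rows = []
        if len(stop_times) >= 2 and len(pop_times) >= 2:
            # channel-averaged raw power TFRs per trial on the 200 Hz signal
            from scipy import signal as sps

            down = int(round(car.fs_hz / fs200))
            x200 = sps.resample_poly(car.data.mean(axis=0), 1, down)
            maps_a = lfp_processing.peri_event_tfrs(
                x200, fs200, stop_times, config.tfr_window_s, freqs
            )
            maps_b = lfp_processing.peri_event_tfrs(
                x200, fs200, pop_times, config.tfr_window_s, freqs
            )
            if len(maps_a) >= 2 and len(maps_b) >= 2:
                db_a = [
                    lfp_processing.normalize_db(m, maps_a, config.tfr_baseline_s)
                    for m in maps_a
                ]
                db_b = [
                    lfp_processing.normalize_db(m, maps_b, config.tfr_baseline_s)
                    for m in maps_b
                ]
                cs = cluster_stats.permutation_null(
                    db_a, db_b, n_perm=config.n_perm, seed=seed
                )
                for c in cs.clusters:
                    f_idx, t_idx = c.pixels[:, 0], c.pixels[:, 1]
                    cluster_rows.append(
                        {
                            "tail": c.tail,
                            "mass": c.mass,
                            "p_value": c.p_value,
                            "n_pixels": len(c.pixels),
                            "f_lo_hz": freqs[f_idx.min()],
                            "f_hi_hz": freqs[f_idx.max()],
                            "t_lo_s": maps_a[0].times_s[t_idx.min()],
                            "t_hi_s": maps_a[0].times_s[t_idx.max()],
                        }
                    )
        pd.DataFrame(
            cluster_rows,
            columns=[
                "tail", "mass", "p_value", "n_pixels",
                "f_lo_hz", "f_hi_hz", "t_lo_s", "t_hi_s",
            ],
        ).to_csv(out / "clusters.csv", index=False)
        done(n_clusters=len(cluster_rows), seed=seed)

        done = _stage("hazard_model")
        seed = derive_seed(config.master_seed, "hazard_model")
        hdesign = hazard_model.build_hazard_design(
            band_powers,
            bundle.trials,
            fs_hz=config.hazard_fs_hz,
            window_s=config.hazard_window_s,
        )
        fit = hazard_model.fit_hazard_model(
            hdesign,
            chains=config.mcmc_chains,
            iters=config.mcmc_iters,
            warmup=config.mcmc_warmup,
            thin=config.mcmc_thin,
            seed=seed,
        )
        fit.table.to_csv(out / "hazard_posterior.csv", index=False)
        hazard_model.summarize_effects(fit).to_csv(
            out / "hazard_effects.csv", index=False
        )
        done(converged=fit.converged, seed=seed, n_bins=hdesign.n_bins)

        log["warnings"] = [str(w.message) for w in caught]

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=_jsonable))
    return log
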