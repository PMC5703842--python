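"""In-memory containers shared across the pipeline.

Trial tables are plain :class:`pandas.DataFrame` objects with the canonical
columns ``trial_id, type, risk, t_start_s, t_stop_s, t_pop_s, outcome,
points``; the dataclasses here hold the array-valued signals (spikes, LFP,
band power, time-frequency maps) together with their sampling metadata.

Time conventions: ``t_start_s`` is on the session clock; ``t_stop_s`` and
``t_pop_s`` are durations relative to trial start. Intervals are half-open
``[start, stop)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "trial_id",
    "type",
    "risk",
    "t_start_s",
    "t_stop_s",
    "t_pop_s",
    "outcome",
    "points",
]


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table for the canonical schema; return it unchanged."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    starts = trials["t_start_s"].to_numpy(float)
    if np.any(np.diff(starts) <= 0):
        raise ValueError("trial start times must be strictly increasing")
    return trials


def trial_end_s(trials: pd.DataFrame) -> np.ndarray:
    """Absolute end time of each trial: stop if present, else pop."""
    rel = trials["t_stop_s"].to_numpy(float)
    pop = trials["t_pop_s"].to_numpy(float)
    rel = np.where(np.isnan(rel), pop, rel)
    return trials["t_start_s"].to_numpy(float) + rel


@dataclass
class SpikeData:
    """Spike timestamps per unit on the session clock.

    Parameters
    ----------
    timestamps
        Mapping ``unit_id -> sorted array of event times in seconds``.
    session_duration_s
        Total recorded duration, used for session-average rates.
    """

    timestamps: dict[str, np.ndarray]
    session_duration_s: float

    def rates(self) -> dict[str, float]:
        """Session-average firing rate (spikes/s) per unit."""
        if self.session_duration_s <= 0:
            raise ValueError("session duration must be positive")
        return {
            u: len(t) / self.session_duration_s for u, t in self.timestamps.items()
        }

    def binned_counts(self, bin_s: float) -> tuple[np.ndarray, np.ndarray]:
        """Counts per uniform bin for all units.

        Returns ``(counts, edges)`` with ``counts`` of shape
        ``(n_units, n_bins)`` in the iteration order of ``timestamps``.
        """
        n_bins = int(np.ceil(self.session_duration_s / bin_s))
        edges = np.arange(n_bins + 1) * bin_s
        counts = np.stack(
            [np.histogram(t, bins=edges)[0] for t in self.timestamps.values()]
        )
        return counts, edges


@dataclass
class LfpRecording:
    """Multichannel LFP: ``data`` is (n_channels, n_samples) at ``fs_hz``."""

    data: np.ndarray
    fs_hz: float
    channel_ids: list[str]
    artifact_mask: np.ndarray | None = None  # bool (n_channels, n_samples), True=bad

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match data rows")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, bool)
            if self.artifact_mask.shape != self.data.shape:
                raise ValueError("artifact mask shape must match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def copy_with(self, **kw) -> "LfpRecording":
        return replace(self, **kw)


@dataclass
class BandPowerSeries:
    """Instantaneous power of one channel in one band.

    ``power`` is sampled at ``fs_hz`` (200 Hz in the standard pipeline) and
    is the squared magnitude of the analytic signal of the band-passed
    channel. ``mask`` marks artifact samples excluded from statistics.
    """

    channel: str
    band: str
    power: np.ndarray
    fs_hz: float
    mask: np.ndarray | None = None  # True = artifact, excluded
    log_scaled: bool = False
    z_scored: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, float)
        if self.mask is None:
            self.mask = np.zeros(self.power.shape, bool)
        else:
            self.mask = np.asarray(self.mask, bool)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.power)) / self.fs_hz

    def valid(self) -> np.ndarray:
        return self.power[~self.mask]


@dataclass
class TimeFrequencyMap:
    """Frequencies x time grid of power, raw or decibel-scaled.

    ``values`` has shape ``(n_freqs, n_times)``. ``kind`` is ``"power"``
    (raw, non-negative), ``"db"`` (baseline-normalized decibels), or
    ``"contrast_db"`` (condition ratio in decibels). ``edge_mask`` flags
    samples within one wavelet half-width of the signal edge.
    """

    freqs_hz: np.ndarray
    times_s: np.ndarray
    values: np.ndarray
    kind: str = "power"
    baseline_s: tuple[float, float] | None = None
    edge_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.times_s = np.asarray(self.times_s, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.freqs_hz), len(self.times_s)):
            raise ValueError("values shape must be (n_freqs, n_times)")
        if self.kind == "power" and np.any(self.values < 0):
            raise ValueError("raw power must be non-negative")

    def copy_with(self, **kw) -> "TimeFrequencyMap":
        return replace(self, **kw)
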