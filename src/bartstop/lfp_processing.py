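"""LFP preprocessing, band power, peri-event traces, and time-frequency maps.

The standard chain: common-average referencing to remove globally shared
artifacts, zero-phase band-pass filtering into canonical bands, anti-aliased
downsampling to 200 Hz, instantaneous power as the squared magnitude of the
analytic (Hilbert) signal, artifact censoring, and peri-event summaries
(median across events of log power, z-scored per channel against the whole
session so channels with different dynamic ranges contribute equally).
Time-frequency maps use a complex Morlet wavelet (w = 9 cycles) on a
log-spaced 2.5-50 Hz grid, shown in decibels relative to a pre-event
baseline interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from bartstop.containers import BandPowerSeries, LfpRecording, TimeFrequencyMap


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError("need 0 <= low < high")


CANONICAL_BANDS = {
    "delta": BandDefinition("delta", 0.1, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 80.0),
}

POWER_FS_HZ = 200.0


def common_average_reference(rec: LfpRecording) -> LfpRecording:
    """Subtract the across-channel mean at every sample.

    Removes artifacts shared identically by all channels. Degenerate for a
    single channel (the output is identically zero); that case is flagged
    with a warning rather than an error.
    """
    if rec.n_channels == 1:
        warnings.warn(
            "common average reference on a single channel zeroes the signal",
            stacklevel=2,
        )
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def _bandpass_sos(band: BandDefinition, fs: float, order: int = 4):
    nyq = fs / 2
    if band.high_hz >= nyq:
        raise ValueError(f"band {band.name!r} upper edge {band.high_hz} Hz >= Nyquist")
    if band.low_hz <= 0:
        return sps.butter(order, band.high_hz / nyq, btype="low", output="sos")
    return sps.butter(
        order, [band.low_hz / nyq, band.high_hz / nyq], btype="band", output="sos"
    )


def band_power(
    rec: LfpRecording,
    band: BandDefinition,
    target_fs_hz: float = POWER_FS_HZ,
) -> list[BandPowerSeries]:
    """Instantaneous band power per channel at 200 Hz.

    Zero-phase (forward-backward) 4th-order Butterworth band-pass at the
    native rate, anti-aliased polyphase downsampling to ``target_fs_hz``,
    then the squared magnitude of the analytic signal. The artifact mask,
    if present, is downsampled alongside (a target sample is masked if any
    native sample it covers is masked).
    """
    sos = _bandpass_sos(band, rec.fs_hz)
    up, down = 1, int(round(rec.fs_hz / target_fs_hz))
    if not np.isclose(rec.fs_hz / down, target_fs_hz):
        raise ValueError("native rate must be an integer multiple of the target rate")
    out = []
    for c in range(rec.n_channels):
        x = sps.sosfiltfilt(sos, rec.data[c])
        if down > 1:
            x = sps.resample_poly(x, up, down)
        power = np.abs(sps.hilbert(x)) ** 2
        mask = None
        if rec.artifact_mask is not None:
            m = rec.artifact_mask[c]
            n_out = len(x)
            pad = (-len(m)) % down
            m = np.concatenate([m, np.zeros(pad, bool)])
            mask = m.reshape(-1, down).any(axis=1)[:n_out]
        out.append(
            BandPowerSeries(
                channel=rec.channel_ids[c],
                band=band.name,
                power=power,
                fs_hz=target_fs_hz,
                mask=mask,
            )
        )
    return out


def detect_artifacts(
    rec: LfpRecording,
    rail_frac: float = 0.999,
    min_rail_s: float = 0.05,
    power_k: float = 10.0,
    power_win_s: float = 0.1,
    guard_s: float = 0.1,
) -> np.ndarray:
    """Mark railing and aberrant-power epochs per channel.

    Railing: |signal| at or above ``rail_frac`` of the channel's absolute
    maximum, sustained for at least ``min_rail_s`` (amplifier saturation).
    Aberrant power: smoothed squared signal more than ``power_k`` robust
    (MAD-based) standard deviations above the channel median. Both are
    padded by ``guard_s`` on each side. Returns a boolean (channels,
    samples) mask, True = artifact.
    """
    fs = rec.fs_hz
    min_run = max(int(min_rail_s * fs), 1)
    guard = int(guard_s * fs)
    win = max(int(power_win_s * fs), 1)
    mask = np.zeros(rec.data.shape, bool)
    kernel = np.ones(win) / win
    for c in range(rec.n_channels):
        x = rec.data[c]
        amax = np.abs(x).max()
        if amax > 0:
            railed = np.abs(x) >= rail_frac * amax
            # keep only runs of sufficient duration
            edges = np.diff(railed.astype(int), prepend=0, append=0)
            starts = np.flatnonzero(edges == 1)
            stops = np.flatnonzero(edges == -1)
            for a, b in zip(starts, stops):
                if b - a >= min_run:
                    mask[c, a:b] = True
        p = np.convolve(x**2, kernel, mode="same")
        med = np.median(p)
        mad = np.median(np.abs(p - med))
        robust_sd = 1.4826 * mad
        if robust_sd > 0:
            mask[c] |= p > med + power_k * robust_sd
    if guard > 0:
        dil = np.ones(2 * guard + 1)
        for c in range(rec.n_channels):
            mask[c] = np.convolve(mask[c].astype(float), dil, mode="same") > 0
    return mask


@dataclass
class PeriEventTrace:
    """Median-across-events trace of (z-scored log) band power."""

    times_s: np.ndarray  # relative to the event
    trace: np.ndarray
    n_events: np.ndarray  # contributing events per time point
    channel: str | None = None
    band: str | None = None


def peri_event_trace(
    power: BandPowerSeries,
    events_s: np.ndarray,
    window_s: tuple[float, float] = (-2.0, 1.0),
    z_score: bool = True,
    min_events: int = 1,
) -> PeriEventTrace:
    """Median across events of the channel's log power around event times.

    Power is log-transformed and, when ``z_score`` is set, standardized
    using the whole-session mean and SD of the unmasked log power — so the
    trace is in channel-comparable units. Masked samples are excluded; time
    points with fewer than ``min_events`` contributing events are NaN.
    """
    fs = power.fs_hz
    logp = np.log(np.clip(power.power, 1e-300, None))
    if z_score:
        valid = logp[~power.mask]
        mu, sd = valid.mean(), valid.std()
        if sd == 0:
            sd = 1.0
        logp = (logp - mu) / sd
    i_pre = int(round(window_s[0] * fs))
    i_post = int(round(window_s[1] * fs))
    offsets = np.arange(i_pre, i_post)
    times = offsets / fs
    n = len(power.power)
    rows = []
    for ev in np.asarray(events_s, float):
        idx = int(round(ev * fs)) + offsets
        ok = (idx >= 0) & (idx < n)
        row = np.full(len(offsets), np.nan)
        good = idx[ok]
        row[ok] = np.where(power.mask[good], np.nan, logp[good])
        rows.append(row)
    stacked = np.vstack(rows) if rows else np.empty((0, len(offsets)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        trace = np.nanmedian(stacked, axis=0) if len(rows) else np.full(len(offsets), np.nan)
    counts = np.sum(~np.isnan(stacked), axis=0)
    trace[counts < min_events] = np.nan
    return PeriEventTrace(
        times_s=times, trace=trace, n_events=counts, channel=power.channel, band=power.band
    )


def average_traces(traces: list[PeriEventTrace]) -> PeriEventTrace:
    """Average peri-event traces across channels on their (z-scored) scale.

    Averaging after per-channel z-scoring gives each channel equal weight
    regardless of its raw dynamic range; pass un-z-scored traces to obtain
    the power-weighted raw average instead.
    """
    if not traces:
        raise ValueError("no traces to average")
    stack = np.vstack([t.trace for t in traces])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return PeriEventTrace(
        times_s=traces[0].times_s,
        trace=mean,
        n_events=np.min(np.vstack([t.n_events for t in traces]), axis=0),
    )


def default_freq_grid(n: int = 40) -> np.ndarray:
    """Logarithmically spaced analysis frequencies, 2.5-50 Hz."""
    return np.geomspace(2.5, 50.0, n)


def _morlet_kernel(f: float, fs: float, w: float) -> np.ndarray:
    """Unit-energy complex Morlet wavelet at frequency ``f`` (w cycles)."""
    sigma_t = w / (2 * np.pi * f)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    k = np.exp(-(t**2) / (2 * sigma_t**2)) * np.exp(2j * np.pi * f * t)
    k /= np.sqrt(np.sum(np.abs(k) ** 2) / fs)  # unit energy
    return k


def wavelet_tfr(
    x: np.ndarray,
    fs_hz: float,
    freqs_hz: np.ndarray | None = None,
    w: float = 9.0,
) -> TimeFrequencyMap:
    """Morlet time-frequency power map of one signal.

    FFT convolution with a unit-energy complex Morlet wavelet (``w`` cycles)
    per frequency, with reflection padding at the edges; power is the
    squared magnitude. Samples within one wavelet half-width of either edge
    are flagged in ``edge_mask``.
    """
    x = np.asarray(x, float)
    if freqs_hz is None:
        freqs_hz = default_freq_grid()
    freqs_hz = np.asarray(freqs_hz, float)
    if np.any(freqs_hz >= fs_hz / 2):
        raise ValueError("analysis frequency at or above Nyquist")
    n = len(x)
    P = np.empty((len(freqs_hz), n))
    edge = np.zeros((len(freqs_hz), n), bool)
    for i, f in enumerate(freqs_hz):
        k = _morlet_kernel(f, fs_hz, w)
        half = len(k) // 2
        pad = min(half, n - 1)
        xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
        conv = sps.fftconvolve(xp, k, mode="same")[pad : pad + n]
        P[i] = np.abs(conv) ** 2
        edge[i, :half] = True
        edge[i, n - half :] = True
    times = np.arange(n) / fs_hz
    return TimeFrequencyMap(
        freqs_hz=freqs_hz, times_s=times, values=P, kind="power", edge_mask=edge
    )


def peri_event_tfrs(
    x: np.ndarray,
    fs_hz: float,
    events_s: np.ndarray,
    window_s: tuple[float, float] = (-2.5, 1.5),
    freqs_hz: np.ndarray | None = None,
    w: float = 9.0,
) -> list[TimeFrequencyMap]:
    """Per-event raw-power TFR snippets with times relative to the event.

    The wavelet transform is computed once on the whole signal and sliced,
    so edge effects only occur at the recording boundaries. Events whose
    window falls outside the recording are skipped.
    """
    tfr = wavelet_tfr(x, fs_hz, freqs_hz, w)
    i_pre = int(round(window_s[0] * fs_hz))
    i_post = int(round(window_s[1] * fs_hz))
    offsets = np.arange(i_pre, i_post)
    rel_times = offsets / fs_hz
    out = []
    n = tfr.values.shape[1]
    for ev in np.asarray(events_s, float):
        idx = int(round(ev * fs_hz)) + offsets
        if idx[0] < 0 or idx[-1] >= n:
            continue
        out.append(
            TimeFrequencyMap(
                freqs_hz=tfr.freqs_hz,
                times_s=rel_times,
                values=tfr.values[:, idx],
                kind="power",
                edge_mask=tfr.edge_mask[:, idx],
            )
        )
    return out


def mean_tfr(maps: list[TimeFrequencyMap]) -> TimeFrequencyMap:
    """Across-trial mean of raw-power maps on a common grid."""
    if not maps:
        raise ValueError("no maps to average")
    vals = np.mean([m.values for m in maps], axis=0)
    return maps[0].copy_with(values=vals)


def baseline_power(
    maps: list[TimeFrequencyMap], baseline_s: tuple[float, float] = (-1.5, -0.5)
) -> np.ndarray:
    """P0(f): mean power per frequency over all trials in the baseline interval."""
    t = maps[0].times_s
    sel = (t >= baseline_s[0]) & (t < baseline_s[1])
    if not sel.any():
        raise ValueError("baseline interval outside the map's time grid")
    return np.mean([m.values[:, sel].mean(axis=1) for m in maps], axis=0)


def normalize_db(
    tfr: TimeFrequencyMap,
    trials: list[TimeFrequencyMap] | None = None,
    baseline_s: tuple[float, float] = (-1.5, -0.5),
) -> TimeFrequencyMap:
    """Baseline-normalize a power map to decibels.

    ``I = 10 log10(P(f, t) / P0(f))`` with ``P0(f)`` the mean power per
    frequency over the baseline interval across all trials (``trials``
    defaults to the map itself). Pixels where P equals the baseline map to
    exactly 0 dB.
    """
    if tfr.kind != "power":
        raise ValueError("normalize_db expects a raw power map")
    P0 = baseline_power(trials if trials is not None else [tfr], baseline_s)
    vals = 10.0 * np.log10(np.clip(tfr.values, 1e-300, None) / P0[:, None])
    return tfr.copy_with(values=vals, kind="db", baseline_s=baseline_s)


def contrast_db(tfr_a: TimeFrequencyMap, tfr_b: TimeFrequencyMap) -> TimeFrequencyMap:
    """Condition contrast in decibels: ``10 log10(P1/P2)``, no baseline."""
    if tfr_a.kind != "power" or tfr_b.kind != "power":
        raise ValueError("contrast_db expects raw power maps")
    if tfr_a.values.shape != tfr_b.values.shape:
        raise ValueError("condition maps must share the same grid")
    vals = 10.0 * np.log10(
        np.clip(tfr_a.values, 1e-300, None) / np.clip(tfr_b.values, 1e-300, None)
    )
    return tfr_a.copy_with(values=vals, kind="contrast_db")
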