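"""Signal conditioning and feature extraction.

EMG: 35 Hz high-pass (6th-order Butterworth, forward-backward zero-lag),
mean subtraction, half-wave rectification, 40 Hz zero-lag low-pass; the
resulting envelope is normalized to a maximum of 1 across all trials within
each participant x side group and integrated in 75-200 / 200-300 / 300-500 ms
bins.

CoM: velocity from Savitzky-Golay-smoothed displacement (3rd order, 49-sample
window — the nearest odd width to the nominal 48); acceleration from
horizontal ground reaction force divided by body mass, platform-relative.

EEG: N1 amplitude/latency as the baseline-referenced minimum of the Cz epoch
in 100-200 ms; beta-band (13-30 Hz) event-related spectral perturbation from
a truncated Gaussian-envelope complex Morlet transform (3 cycles at 6 Hz
rising linearly to 23 at 50 Hz, 256 ms window), expressed in dB relative to
the -400..-100 ms pre-perturbation baseline and summarised in
50-150 / 150-250 / 250-500 ms bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .timeseries import TimeSeries

__all__ = [
    "BinnedResponse",
    "CorticalFeatures",
    "ErspMatrix",
    "EMG_BINS",
    "BETA_BINS",
    "process_emg",
    "normalize_emg",
    "integrate_bins",
    "savgol_velocity",
    "com_acceleration",
    "n1_features",
    "ersp",
    "beta_power",
]

EMG_BINS: Tuple[Tuple[float, float], ...] = ((75.0, 200.0), (200.0, 300.0), (300.0, 500.0))
BETA_BINS: Tuple[Tuple[float, float], ...] = ((50.0, 150.0), (150.0, 250.0), (250.0, 500.0))

_BASELINE = (-400.0, -100.0)


@dataclass(frozen=True)
class BinnedResponse:
    """Per-bin summary of a response trace (integrated EMG or mean beta power)."""

    bin_edges: Tuple[Tuple[float, float], ...]
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        edges = tuple((float(a), float(b)) for a, b in self.bin_edges)
        for (a, b) in edges:
            if b <= a:
                raise ValueError("each bin must have start < end")
        for (_, b0), (a1, _) in zip(edges, edges[1:]):
            if a1 < b0:
                raise ValueError("bins must be non-overlapping and ascending")
        vals = tuple(float(v) for v in self.values)
        if len(vals) != len(edges) or not all(np.isfinite(vals)):
            raise ValueError("one finite value per bin required")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class CorticalFeatures:
    """Perturbation-evoked N1 amplitude (uV, baseline-relative) and latency (ms)."""

    n1_amplitude: float
    n1_latency: float

    def __post_init__(self) -> None:
        if not (100.0 - 1e-9 <= self.n1_latency <= 200.0 + 1e-9):
            raise ValueError("N1 latency must lie in the 100-200 ms search window")


@dataclass(frozen=True)
class ErspMatrix:
    """Time-frequency power change (dB from baseline), freqs x times."""

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        times = np.asarray(self.times, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if np.any(np.diff(freqs) <= 0) or freqs[0] < 6 - 1e-9 or freqs[-1] > 50 + 1e-9:
            raise ValueError("freqs must be ascending within [6, 50] Hz")
        if power.shape != (freqs.size, times.size):
            raise ValueError("power must be (n_freqs, n_times)")
        if not np.all(np.isfinite(power)):
            raise ValueError("power must be finite")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "power", power)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def process_emg(raw: TimeSeries) -> TimeSeries:
    """Raw EMG (1000 Hz, -400..1400 ms epoch) -> normalized-ready envelope.

    High-pass 35 Hz, mean-subtract, half-wave rectify, low-pass 40 Hz; both
    filters 6th-order Butterworth applied forward-backward (zero phase lag).
    """
    if abs(raw.fs - 1000.0) > 1e-6:
        raise ValueError("EMG must be sampled at 1000 Hz; resample first")
    sos_hp = sps.butter(6, 35.0, btype="highpass", fs=raw.fs, output="sos")
    x = sps.sosfiltfilt(sos_hp, raw.values)
    x = x - x.mean()
    x = np.maximum(0.0, x)
    sos_lp = sps.butter(6, 40.0, btype="lowpass", fs=raw.fs, output="sos")
    env = sps.sosfiltfilt(sos_lp, x)
    return raw.with_values(env)


def normalize_emg(
    trials: Sequence[TimeSeries],
    groups: Sequence[Hashable] | None = None,
) -> List[TimeSeries]:
    """Divide every trial by the maximum over all trials in its group.

    ``groups`` assigns each trial to a participant x side group; omitted, all
    trials form one group. After normalization the group maximum is exactly 1.
    """
    if not trials:
        raise ValueError("at least one trial required")
    if groups is None:
        groups = [0] * len(trials)
    if len(groups) != len(trials):
        raise ValueError("one group label per trial required")
    divisor: Dict[Hashable, float] = {}
    for ts, g in zip(trials, groups):
        divisor[g] = max(divisor.get(g, -np.inf), float(np.max(ts.values)))
    for g, m in divisor.items():
        if m <= 0:
            raise ValueError(f"group {g!r} has non-positive maximum; cannot normalize")
    return [ts.with_values(ts.values / divisor[g]) for ts, g in zip(trials, groups)]


def integrate_bins(
    envelope: TimeSeries, edges: Sequence[Tuple[float, float]] = EMG_BINS
) -> BinnedResponse:
    """Trapezoidal integral of the envelope over each [start, end] ms bin."""
    t = envelope.times
    vals = []
    for (a, b) in edges:
        if a < envelope.t0 - 1e-9 or b > envelope.t_end + 1e-9:
            raise ValueError(f"bin ({a}, {b}) ms lies outside the epoch")
        # integrate on the exact bin by interpolating the edge samples
        grid = t[(t > a) & (t < b)]
        tt = np.concatenate(([a], grid, [b]))
        yy = np.interp(tt, t, envelope.values)
        vals.append(float(np.trapezoid(yy, tt)))
    return BinnedResponse(tuple(edges), tuple(vals))


# ---------------------------------------------------------------------------
# CoM kinematics
# ---------------------------------------------------------------------------

def savgol_velocity(displacement: TimeSeries, window: int = 49, polyorder: int = 3) -> TimeSeries:
    """CoM velocity as the Savitzky-Golay smoothed derivative of displacement.

    The derivative comes from the SG convolution itself (deriv=1), which
    reproduces derivatives of polynomials up to the fit order exactly on
    interior samples. The nominal 48-sample window is widened to the nearest
    odd length (49) so the window has a centre sample.
    """
    if window % 2 == 0:
        window += 1
    if len(displacement) <= window:
        raise ValueError("displacement series shorter than the smoothing window")
    v = sps.savgol_filter(
        displacement.values, window, polyorder, deriv=1, delta=1.0 / displacement.fs
    )
    return displacement.with_values(v)


def com_acceleration(grf: TimeSeries, mass: float, platform_acc: TimeSeries) -> TimeSeries:
    """Platform-relative CoM acceleration in cm/s^2.

    a(t) = GRF(t) / m - a_platform(t), with GRF in newtons (horizontal
    component), mass in kg and platform acceleration in cm/s^2.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if not grf.same_grid(platform_acc):
        raise ValueError("GRF and platform acceleration must share a grid")
    a_m_s2 = grf.values / mass  # m/s^2
    return grf.with_values(a_m_s2 * 100.0 - platform_acc.values)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def n1_features(
    cz_epoch: TimeSeries,
    search: Tuple[float, float] = (100.0, 200.0),
    baseline: Tuple[float, float] = _BASELINE,
) -> CorticalFeatures:
    """N1 amplitude and latency from a Cz epoch.

    Amplitude is the epoch minimum within the search window minus the mean
    over the pre-perturbation baseline; latency is the time of that minimum
    (earliest sample on ties).
    """
    if cz_epoch.t0 > baseline[0] + 1e-9 or cz_epoch.t_end < search[1] - 1e-9:
        raise ValueError("epoch must cover the baseline and the N1 search window")
    t = cz_epoch.times
    base = cz_epoch.values[(t >= baseline[0] - 1e-9) & (t <= baseline[1] + 1e-9)]
    win_mask = (t >= search[0] - 1e-9) & (t <= search[1] + 1e-9)
    win_vals = cz_epoch.values[win_mask]
    win_t = t[win_mask]
    i = int(np.argmin(win_vals))  # argmin returns the first (earliest) minimum
    return CorticalFeatures(float(win_vals[i] - base.mean()), float(win_t[i]))


def wavelet_cycles(freq: float) -> float:
    """Cycles per wavelet: 3 at 6 Hz rising linearly to 23 at 50 Hz."""
    return 3.0 + (freq - 6.0) * (23.0 - 3.0) / (50.0 - 6.0)


def _morlet_kernel(freq: float, cycles: float, fs: float, window_ms: float) -> np.ndarray:
    """Complex Morlet, Gaussian envelope, truncated to the analysis window."""
    half = window_ms / 2000.0  # s
    t = np.arange(-half, half + 0.5 / fs, 1.0 / fs)
    sigma_t = cycles / (2.0 * np.pi * freq)
    kern = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return kern / np.sqrt(np.sum(np.abs(kern) ** 2))


def ersp(
    epoch: TimeSeries,
    freqs: Sequence[float] | None = None,
    window_ms: float = 256.0,
    baseline: Tuple[float, float] = _BASELINE,
) -> ErspMatrix:
    """Event-related spectral perturbation of a single epoch.

    Wavelet cycles grow linearly from 3 at 6 Hz to 23 at 50 Hz. Power is
    expressed in dB and referenced, per frequency, to the mean baseline dB
    (so the baseline mean is 0 dB by construction). The time grid keeps only
    samples where the full 256 ms window fits inside the epoch.
    """
    if freqs is None:
        freqs = np.arange(6.0, 50.0 + 1e-9, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    half_n = int(round(window_ms / 2.0 * epoch.fs / 1000.0))
    if len(epoch) <= 2 * half_n:
        raise ValueError("epoch too short for the sliding analysis window")
    times = epoch.times[half_n : len(epoch) - half_n]
    power_db = np.empty((freqs.size, times.size))
    for i, f in enumerate(freqs):
        kern = _morlet_kernel(f, wavelet_cycles(f), epoch.fs, window_ms)
        conv = sps.fftconvolve(epoch.values, np.conj(kern[::-1]), mode="valid")
        p = np.abs(conv[: times.size]) ** 2
        power_db[i] = 10.0 * np.log10(np.maximum(p, 1e-300))
    bmask = (times >= baseline[0] - 1e-9) & (times <= baseline[1] + 1e-9)
    if not bmask.any():
        # epoch starts too late for the nominal baseline; use what is available
        bmask = times <= baseline[1] + 1e-9
    power_db -= power_db[:, bmask].mean(axis=1, keepdims=True)
    return ErspMatrix(freqs, times, power_db)


def beta_power(
    mat: ErspMatrix,
    band: Tuple[float, float] = (13.0, 30.0),
    bins: Sequence[Tuple[float, float]] = BETA_BINS,
) -> Tuple[TimeSeries, BinnedResponse]:
    """Average the ERSP across the beta band and summarise in time bins.

    Returns the beta-power time course (dB) and the per-bin time means.
    """
    sel = (mat.freqs >= band[0] - 1e-9) & (mat.freqs <= band[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"no sampled frequencies in the {band} Hz band")
    trace = mat.power[sel].mean(axis=0)
    fs = 1000.0 / float(np.mean(np.diff(mat.times)))
    ts = TimeSeries(trace, fs, float(mat.times[0]))
    vals = []
    for (a, b) in bins:
        m = (mat.times >= a - 1e-9) & (mat.times <= b + 1e-9)
        if not m.any():
            raise ValueError(f"bin ({a}, {b}) ms outside the ERSP time grid")
        vals.append(float(trace[m].mean()))
    return ts, BinnedResponse(tuple(bins), tuple(vals))
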