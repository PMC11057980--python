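"""Uniformly sampled time series aligned to perturbation onset.

Every signal in the pipeline — CoM kinematics, EMG envelopes, Cz epochs,
beta-power traces — is carried as a :class:`TimeSeries`: an immutable array of
samples with a sampling rate ``fs`` (Hz) and the time of the first sample
``t0`` in milliseconds relative to perturbation onset (t = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeSeries", "ComKinematics", "delay_shift", "resample"]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    values : array-like
        Samples, at least two, all finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float, optional
        Time of the first sample in ms relative to perturbation onset.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("TimeSeries requires a 1-D array of length >= 2")
        if not np.all(np.isfinite(vals)):
            raise ValueError("TimeSeries samples must be finite")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise ValueError("sampling rate must be a positive finite number")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "t0", float(self.t0))

    # -- grid helpers -----------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def dt_ms(self) -> float:
        """Sample spacing in milliseconds."""
        return 1000.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to perturbation onset."""
        return self.t0 + np.arange(self.values.size) * self.dt_ms

    @property
    def t_end(self) -> float:
        return self.t0 + (self.values.size - 1) * self.dt_ms

    def same_grid(self, other: "TimeSeries", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and abs(self.fs - other.fs) <= tol * self.fs
            and abs(self.t0 - other.t0) <= tol * max(1.0, abs(self.t0))
        )

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """Return a series on the same grid with new samples."""
        return TimeSeries(values, self.fs, self.t0)

    def window_mask(self, t_start: float, t_end: float) -> np.ndarray:
        """Boolean mask of samples with t_start <= t <= t_end (ms)."""
        t = self.times
        return (t >= t_start - 1e-9) & (t <= t_end + 1e-9)

    def crop(self, t_start: float, t_end: float) -> "TimeSeries":
        mask = self.window_mask(t_start, t_end)
        if mask.sum() < 2:
            raise ValueError(f"window [{t_start}, {t_end}] ms not covered by epoch")
        idx = np.flatnonzero(mask)
        return TimeSeries(self.values[idx], self.fs, self.times[idx[0]])


@dataclass(frozen=True)
class ComKinematics:
    """Aligned CoM balance-error channels: displacement, velocity, acceleration.

    The three channels must share sampling rate, origin and length. Units are
    cm, cm/s and cm/s^2 relative to the base of support.
    """

    d: TimeSeries
    v: TimeSeries
    a: TimeSeries

    def __post_init__(self) -> None:
        if not (self.d.same_grid(self.v) and self.d.same_grid(self.a)):
            raise ValueError("d, v, a must share sampling rate, t0 and length")

    @property
    def fs(self) -> float:
        return self.d.fs

    @property
    def t0(self) -> float:
        return self.d.t0

    @property
    def times(self) -> np.ndarray:
        return self.d.times

    def __len__(self) -> int:
        return len(self.d)


def delay_shift(x: TimeSeries, delay_ms: float) -> TimeSeries:
    """Delay a signal: output(t) = x(t - delay_ms).

    Fractional-sample delays are realised by linear interpolation so that the
    delay is a continuous, optimizable parameter. Samples that would need
    pre-epoch history take the first epoch value (quiet-stance assumption).
    """
    if delay_ms < 0:
        raise ValueError("delay must be non-negative")
    shift = delay_ms * x.fs / 1000.0
    if shift == 0.0:
        return x
    idx = np.arange(len(x), dtype=float)
    out = np.interp(idx - shift, idx, x.values)
    return x.with_values(out)


def resample(x: TimeSeries, fs: float, t_start: float, t_end: float) -> TimeSeries:
    """Linearly interpolate a signal onto a new uniform grid.

    The common analysis grid is 1000 Hz on the EMG epoch (-400..+1400 ms);
    values outside the source support are held at the nearest edge sample.
    """
    if fs <= 0:
        raise ValueError("target sampling rate must be positive")
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    n = int(round((t_end - t_start) * fs / 1000.0)) + 1
    t_new = t_start + np.arange(n) * 1000.0 / fs
    out = np.interp(t_new, x.times, x.values)
    return TimeSeries(out, fs, t_start)
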