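"""Independent brute-force oracles for the forward models, objective and AIC.

Everything here is written directly from the model definitions as explicit
per-sample loops, deliberately sharing no code with the package internals, so
agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def sample_delayed(values: np.ndarray, i: int, shift_samples: float) -> float:
    """values[i - shift] with linear interpolation and first-value extension."""
    q = i - shift_samples
    if q <= 0:
        return float(values[0])
    lo = int(math.floor(q))
    if lo >= len(values) - 1:
        return float(values[-1])
    frac = q - lo
    return float(values[lo] * (1.0 - frac) + values[lo + 1] * frac)


def brute_reconstruct(
    com,
    gains1=(0.0, 0.0, 0.0),
    lambda1_ms: float = 0.0,
    gains2=None,
    lambda2_ms: float = 0.0,
    cortical=None,
    k_signal: float = 0.0,
    delta_ms: float = 0.0,
    polarity: int = +1,
) -> np.ndarray:
    """Sample-by-sample evaluation of any delayed-feedback reconstruction.

    out[i] = polarity * max(0, sum_j g1_j * ch_j[i - l1] (+ second loop)).
    """
    fs = com.d.fs
    n = len(com.d)
    chans = (com.d.values, com.v.values, com.a.values)
    s1 = lambda1_ms * fs / 1000.0
    s2 = lambda2_ms * fs / 1000.0
    sc = delta_ms * fs / 1000.0
    out = np.empty(n)
    for i in range(n):
        pre = 0.0
        for g, ch in zip(gains1, chans):
            pre += g * sample_delayed(ch, i, s1)
        if gains2 is not None:
            for g, ch in zip(gains2, chans):
                pre += g * sample_delayed(ch, i, s2)
        if cortical is not None:
            pre += k_signal * sample_delayed(cortical.values, i, sc)
        out[i] = polarity * max(0.0, pre)
    return out


def brute_objective(observed, reconstruction, gains, mu_s, mu_m, mu_k, t_start, t_end):
    """Literal evaluation of the penalized objective on [t_start, t_end]."""
    t = observed.times
    idx = [i for i in range(len(t)) if t_start - 1e-9 <= t[i] <= t_end + 1e-9]
    e = [observed.values[i] - reconstruction.values[i] for i in idx]
    dt = 1.0 / observed.fs
    sq = sum(0.5 * (e[j] ** 2 + e[j + 1] ** 2) * dt for j in range(len(e) - 1))
    return mu_s * sq + mu_m * max(abs(v) for v in e) + mu_k * sum(g * g for g in gains)


def brute_aic(ssr: float, n_data: int, n_params: int) -> float:
    return n_data * math.log(ssr / n_data) + 2 * n_params
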