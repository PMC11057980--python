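"""Synthetic perturbation trials with known ground truth.

The generator emulates backward support-surface translations at the three
study magnitudes (small 7.7 cm / 16.0 cm/s / 0.23 g; medium and large at the
midpoints of the height-adjusted ranges), a stabilised linear CoM plant that
returns the balance error toward zero, and muscle / Cz / beta traces produced
by the forward SRMs themselves plus signal-dependent Gaussian noise. Because
the traces are generated by the very equations the fitter assumes, recovered
parameters can be compared against the stored truth, which is the package's
main validation surface.

Sign conventions: backward platform translation is the negative direction, so
the platform-frame CoM error (x'' = -K x - B x' - a_platform) is positive —
forward lean relative to the feet — and the agonist (medial gastrocnemius)
drive is positive under non-negative kinematic gains. EMG surrogates live in
the normalized envelope domain [0, 1]; Cz in microvolts (negative-going N1);
beta in dB.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .forward import (
    FeedbackGains,
    LoopTiming,
    SRMParams,
    SRMSpec,
    Variant,
    reconstruct,
)
from .timeseries import ComKinematics, TimeSeries

__all__ = [
    "G_CM",
    "PerturbationMagnitude",
    "PlantParams",
    "NoiseModel",
    "TrialTruth",
    "SyntheticTrial",
    "MAGNITUDES",
    "platform_profile",
    "accel_phase_duration",
    "com_response",
    "make_com",
    "generate_trial",
    "generate_dataset",
]

G_CM = 981.0  # cm/s^2 per g

EPOCH = (-400.0, 1400.0)  # ms, the EMG epoch used as the common analysis grid


@dataclass(frozen=True)
class PerturbationMagnitude:
    """Platform translation magnitude: total displacement (cm), peak
    velocity (cm/s), peak acceleration (g)."""

    displacement: float
    peak_velocity: float
    peak_acceleration: float

    def __post_init__(self) -> None:
        if min(self.displacement, self.peak_velocity, self.peak_acceleration) <= 0:
            raise ValueError("magnitude components must be positive")
        a = self.peak_acceleration * G_CM
        if self.displacement < self.peak_velocity**2 / a - 1e-12:
            raise ValueError(
                "infeasible magnitude: displacement < peak_velocity^2 / peak_acceleration"
            )


MAGNITUDES: Dict[str, PerturbationMagnitude] = {
    "small": PerturbationMagnitude(7.7, 16.0, 0.23),
    "medium": PerturbationMagnitude(13.8, 29.0, 0.415),
    "large": PerturbationMagnitude(20.15, 40.5, 0.59),
}


@dataclass(frozen=True)
class PlantParams:
    """Stabilised linear CoM-error plant.

    effective_stiffness K (s^-2) and damping B (s^-1) give a damped return of
    the balance error toward zero; participants in the protocol do not fall,
    so the generator's plant must be stable.
    """

    effective_stiffness: float = 20.0
    damping: float = 6.0
    pendulum_length: float = 1.0  # m; informational, not used by the linear plant

    def __post_init__(self) -> None:
        if self.effective_stiffness <= 0 or self.damping <= 0:
            raise ValueError("plant must be stable: stiffness > 0 and damping > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Signal-dependent Gaussian noise: sd(t) = sigma0 * ref + sigma_prop * |clean(t)|.

    ``ref`` is 1 for the normalized EMG surrogate and the trace's peak
    amplitude for Cz / beta, so sigma0 reads as a fraction of full scale.
    """

    sigma0: float = 0.01
    sigma_prop: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.sigma_prop < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass(frozen=True)
class TrialTruth:
    """Ground-truth parameter sets generating one trial's traces."""

    muscle: SRMParams
    cz: SRMParams
    beta: SRMParams


@dataclass(frozen=True)
class SyntheticTrial:
    com: ComKinematics
    emg: TimeSeries
    cz: TimeSeries
    beta: TimeSeries
    truth: TrialTruth
    magnitude: str
    participant: str
    seed: int

    def noiseless(self) -> Dict[str, TimeSeries]:
        """Regenerate the clean traces from the stored truth (bit-exact)."""
        return _clean_traces(self.com, self.truth)


# ---------------------------------------------------------------------------
# platform and plant
# ---------------------------------------------------------------------------

def accel_phase_duration(mag: PerturbationMagnitude) -> float:
    """Duration (s) of the constant-acceleration ramp: V / A."""
    return mag.peak_velocity / (mag.peak_acceleration * G_CM)


def platform_profile(
    mag: PerturbationMagnitude,
    fs: float = 1000.0,
    epoch: Tuple[float, float] = EPOCH,
    direction: int = -1,
) -> ComKinematics:
    """Trapezoidal-velocity platform translation starting at t = 0.

    Constant acceleration to peak velocity, a constant-velocity plateau, and
    a mirrored deceleration, evaluated analytically per sample so the
    displacement / velocity / acceleration extrema match the requested
    triplet exactly. ``direction`` -1 (default) is the backward translation.
    """
    if direction not in (-1, +1):
        raise ValueError("direction must be +1 or -1")
    A = mag.peak_acceleration * G_CM
    V = mag.peak_velocity
    D = mag.displacement
    t1 = V / A
    t2 = (D - V**2 / A) / V
    n = int(round((epoch[1] - epoch[0]) * fs / 1000.0)) + 1
    t = (epoch[0] + np.arange(n) * 1000.0 / fs) / 1000.0  # s
    a = np.zeros(n)
    v = np.zeros(n)
    d = np.zeros(n)
    d1 = 0.5 * A * t1**2

    ph1 = (t >= 0) & (t < t1)
    a[ph1] = A
    v[ph1] = A * t[ph1]
    d[ph1] = 0.5 * A * t[ph1] ** 2

    ph2 = (t >= t1) & (t < t1 + t2)
    v[ph2] = V
    d[ph2] = d1 + V * (t[ph2] - t1)

    ph3 = (t >= t1 + t2) & (t < 2 * t1 + t2)
    tau = t[ph3] - (t1 + t2)
    a[ph3] = -A
    v[ph3] = V - A * tau
    d[ph3] = d1 + V * t2 + V * tau - 0.5 * A * tau**2

    d[t >= 2 * t1 + t2] = D

    s = float(direction)
    return ComKinematics(
        TimeSeries(s * d, fs, epoch[0]),
        TimeSeries(s * v, fs, epoch[0]),
        TimeSeries(s * a, fs, epoch[0]),
    )


def com_response(platform: ComKinematics, plant: PlantParams = PlantParams()) -> ComKinematics:
    """CoM balance error from the platform acceleration.

    Integrates x'' = -K x - B x' - a_platform(t) from rest with an exact
    zero-order-hold discretisation of the linear plant, so the run is
    deterministic and the acceleration keeps a sharp transient time-locked to
    platform-acceleration onset (needed for delay identifiability).
    """
    K, B = plant.effective_stiffness, plant.damping
    fs = platform.fs
    Ac = np.array([[0.0, 1.0], [-K, -B]])
    Bc = np.array([[0.0], [1.0]])
    Ad, Bd, *_ = sps.cont2discrete(
        (Ac, Bc, np.eye(2), np.zeros((2, 1))), 1.0 / fs, method="zoh"
    )
    u = -platform.a.values
    n = len(platform)
    state = np.zeros((n, 2))
    x = np.zeros(2)
    for i in range(n - 1):
        state[i] = x
        x = Ad @ x + Bd[:, 0] * u[i]
    state[n - 1] = x
    d = state[:, 0]
    v = state[:, 1]
    a = -K * d - B * v + u
    t0 = platform.t0
    return ComKinematics(
        TimeSeries(d, fs, t0), TimeSeries(v, fs, t0), TimeSeries(a, fs, t0)
    )


def make_com(
    magnitude: PerturbationMagnitude | str = "small",
    plant: PlantParams = PlantParams(),
    fs: float = 1000.0,
    epoch: Tuple[float, float] = EPOCH,
) -> ComKinematics:
    """Convenience: platform profile -> CoM response for one magnitude."""
    mag = MAGNITUDES[magnitude] if isinstance(magnitude, str) else magnitude
    return com_response(platform_profile(mag, fs=fs, epoch=epoch), plant)


# ---------------------------------------------------------------------------
# trial and dataset generation
# ---------------------------------------------------------------------------

def _clean_traces(com: ComKinematics, truth: TrialTruth) -> Dict[str, TimeSeries]:
    cz = reconstruct(truth.cz, com)
    beta = reconstruct(truth.beta, com)
    variant = truth.muscle.spec.variant
    cortical = cz if variant is Variant.HSRM_N1 else beta if variant is Variant.HSRM_BETA else None
    emg = reconstruct(truth.muscle, com, cortical=cortical)
    return {"emg": emg, "cz": cz, "beta": beta}


def generate_trial(
    com: ComKinematics,
    truth: TrialTruth,
    noise: NoiseModel = NoiseModel(),
    magnitude: str = "small",
    participant: str = "P01",
) -> SyntheticTrial:
    """Forward-generate one trial: clean SRM traces plus seeded noise.

    EMG noise is clipped at zero (envelopes are non-negative); Cz and beta
    are left unclipped.
    """
    clean = _clean_traces(com, truth)
    rng = np.random.default_rng(noise.seed)

    def noisy(ts: TimeSeries, ref: float, clip: bool) -> TimeSeries:
        sd = noise.sigma0 * ref + noise.sigma_prop * np.abs(ts.values)
        vals = ts.values + rng.normal(0.0, 1.0, len(ts)) * sd
        if clip:
            vals = np.maximum(0.0, vals)
        return ts.with_values(vals)

    peak = lambda ts: max(float(np.max(np.abs(ts.values))), 1e-12)
    emg = noisy(clean["emg"], 1.0, clip=True)
    cz = noisy(clean["cz"], peak(clean["cz"]), clip=False)
    beta = noisy(clean["beta"], peak(clean["beta"]), clip=False)
    return SyntheticTrial(com, emg, cz, beta, truth, magnitude, participant, noise.seed)


_MAG_LOOP2_SCALE = {"small": 0.6, "medium": 1.0, "large": 1.4}


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def draw_participant_truth(
    rng: np.random.Generator,
    muscle_variant: Variant | str = Variant.HSRM_KIN,
    accel_only_loop2: bool = True,
) -> Dict[str, object]:
    """Draw one participant's ground-truth parameters from documented ranges.

    lambda_bs ~ U[90, 120] ms, lambda_c ~ U[180, 280] ms, tau_c ~ U[60, 100]
    ms; kinematic gains log-uniform over ranges that put the simulated
    envelope peak at O(0.5) normalized units for the small perturbation.
    """
    variant = Variant(muscle_variant)
    lam_bs = rng.uniform(90.0, 120.0)
    lam_c = rng.uniform(180.0, 280.0)
    tau_c = rng.uniform(60.0, 100.0)
    g1 = FeedbackGains(
        k_d=_loguniform(rng, 1e-2, 6e-2),
        k_v=_loguniform(rng, 5e-3, 2e-2),
        k_a=_loguniform(rng, 1e-3, 3e-3),
    )
    k_a2_base = _loguniform(rng, 1e-3, 3e-3)
    cz_truth = SRMParams(
        SRMSpec.for_variant(Variant.CSRM_N1, accel_only_loop1=True),
        FeedbackGains(k_a=_loguniform(rng, 1e-2, 3e-2)),
        LoopTiming(lambda_bs=0.0, tau_c=tau_c),
    )
    beta_truth = SRMParams(
        SRMSpec.for_variant(Variant.CSRM_BETA, accel_only_loop1=True),
        FeedbackGains(k_a=_loguniform(rng, 5e-3, 1.5e-2)),
        LoopTiming(lambda_bs=0.0, tau_c=tau_c),
    )
    k_signal = None
    if variant is Variant.HSRM_N1:
        k_signal = -rng.uniform(0.02, 0.06)  # negative: N1 trough drives excitation
    elif variant is Variant.HSRM_BETA:
        k_signal = rng.uniform(0.05, 0.15)
    return {
        "variant": variant,
        "accel_only_loop2": accel_only_loop2,
        "lambda_bs": lam_bs,
        "lambda_c": lam_c,
        "tau_c": tau_c,
        "gains1": g1,
        "k_a2_base": k_a2_base,
        "k_signal": k_signal,
        "cz": cz_truth,
        "beta": beta_truth,
    }


def _truth_for_cell(draw: Dict[str, object], magnitude: str) -> TrialTruth:
    variant: Variant = draw["variant"]
    scale = _MAG_LOOP2_SCALE.get(magnitude, 1.0)
    timing = LoopTiming(
        lambda_bs=draw["lambda_bs"],
        lambda_c=draw["lambda_c"],
        tau_c=draw["tau_c"],
    )
    if variant is Variant.MSRM:
        muscle = SRMParams(
            SRMSpec.for_variant(Variant.MSRM),
            draw["gains1"],
            LoopTiming(lambda_bs=draw["lambda_bs"]),
        )
    elif variant is Variant.HSRM_KIN:
        spec = SRMSpec.for_variant(Variant.HSRM_KIN, accel_only_loop2=draw["accel_only_loop2"])
        gains2 = FeedbackGains(k_a=draw["k_a2_base"] * scale)
        muscle = SRMParams(spec, draw["gains1"], timing, gains2=gains2)
    else:
        spec = SRMSpec.for_variant(variant)
        muscle = SRMParams(spec, draw["gains1"], timing, k_signal=draw["k_signal"] * scale)
    return TrialTruth(muscle=muscle, cz=draw["cz"], beta=draw["beta"])


def generate_dataset(
    n_participants: int = 17,
    magnitudes: Optional[Sequence[str]] = None,
    trials_per_cell: int = 8,
    base_seed: int = 0,
    muscle_variant: Variant | str = Variant.HSRM_KIN,
    accel_only_loop2: bool = True,
    noise: NoiseModel = NoiseModel(),
    plant: PlantParams = PlantParams(),
    fs: float = 1000.0,
    epoch: Tuple[float, float] = EPOCH,
) -> Tuple[List[SyntheticTrial], Dict]:
    """Generate a full synthetic study: participants x magnitudes x trials.

    Defaults mirror the study design (17 participants, 3 magnitudes, 8
    non-stepping trials per cell). The second-loop gain scales with
    perturbation magnitude, emulating the growth of the second burst with
    balance challenge. Returns the trials plus a manifest of truths and
    seeds; the same base_seed reproduces both exactly.
    """
    if n_participants < 1 or trials_per_cell < 1:
        raise ValueError("counts must be >= 1")
    labels = list(magnitudes) if magnitudes is not None else list(MAGNITUDES)
    master = np.random.default_rng(base_seed)
    coms = {lab: make_com(lab, plant, fs, epoch) for lab in labels}
    trials: List[SyntheticTrial] = []
    manifest: Dict = {"base_seed": base_seed, "participants": {}}
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        pseed = int(master.integers(0, 2**31 - 1))
        draw = draw_participant_truth(
            np.random.default_rng(pseed), muscle_variant, accel_only_loop2
        )
        pman: Dict = {"seed": pseed, "cells": {}}
        for lab in labels:
            truth = _truth_for_cell(draw, lab)
            cell_seeds = [int(master.integers(0, 2**31 - 1)) for _ in range(trials_per_cell)]
            for s in cell_seeds:
                trial_noise = NoiseModel(noise.sigma0, noise.sigma_prop, seed=s)
                trials.append(
                    generate_trial(coms[lab], truth, trial_noise, magnitude=lab, participant=pid)
                )
            pman["cells"][lab] = {
                "truth": {
                    "muscle": truth.muscle.to_dict(),
                    "cz": truth.cz.to_dict(),
                    "beta": truth.beta.to_dict(),
                },
                "trial_seeds": cell_seeds,
            }
        manifest["participants"][pid] = pman
    return trials, manifest
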