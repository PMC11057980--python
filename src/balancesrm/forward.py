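"""Forward sensorimotor response models (SRMs).

An SRM reconstructs a perturbation-evoked neurophysiological signal as a
delayed, gain-weighted, half-wave-rectified sum of CoM balance-error
kinematics. Variants:

``mSRM``
    single subcortical loop driving muscle activity:
    emg(t) = max(0, k_d d(t-l_bs) + k_v v(t-l_bs) + k_a a(t-l_bs))
``hSRM-kin``
    adds a second, longer-latency kinematic loop (delay l_c > l_bs) inside
    the same rectifier, modelling a transcortical contribution.
``hSRM-N1`` / ``hSRM-beta``
    the second loop instead feeds a measured cortical signal (Cz N1 trace or
    beta-band power) scaled by a sign-free gain and delayed by the efferent
    delay d_c = l_c - tau_c.
``cSRM-N1`` / ``cSRM-beta``
    the single-loop model retargeted at the cortical signal itself, with the
    shorter afferent delay tau_c; the Cz variant carries polarity -1 because
    the N1 is a negative-going potential (the rectified reconstruction models
    the negated trace).

All functions are pure and deterministic; rectification is applied once, to
the full pre-rectification sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import FrozenSet, Optional

import numpy as np

from .timeseries import ComKinematics, TimeSeries, delay_shift

__all__ = [
    "Variant",
    "SRMSpec",
    "FeedbackGains",
    "LoopTiming",
    "SRMParams",
    "reconstruct_msrm",
    "reconstruct_hsrm_kin",
    "reconstruct_hsrm_cortical",
    "reconstruct_csrm",
    "reconstruct",
    "rectify",
]

KINEMATIC = frozenset({"d", "v", "a"})
CORTICAL = frozenset({"cortical"})


class Variant(str, Enum):
    MSRM = "mSRM"
    HSRM_KIN = "hSRM-kin"
    HSRM_N1 = "hSRM-N1"
    HSRM_BETA = "hSRM-beta"
    CSRM_N1 = "cSRM-N1"
    CSRM_BETA = "cSRM-beta"

    @property
    def is_single_loop(self) -> bool:
        return self in (Variant.MSRM, Variant.CSRM_N1, Variant.CSRM_BETA)

    @property
    def is_cortical_target(self) -> bool:
        return self in (Variant.CSRM_N1, Variant.CSRM_BETA)

    @property
    def uses_cortical_predictor(self) -> bool:
        return self in (Variant.HSRM_N1, Variant.HSRM_BETA)

    @property
    def polarity(self) -> int:
        """Sign of the reported reconstruction (-1 for the negative-going N1)."""
        return -1 if self is Variant.CSRM_N1 else +1


@dataclass(frozen=True)
class SRMSpec:
    """Which model variant and which predictors are active in each loop."""

    variant: Variant
    loop1_predictors: FrozenSet[str] = KINEMATIC
    loop2_predictors: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        variant = Variant(self.variant)
        object.__setattr__(self, "variant", variant)
        object.__setattr__(self, "loop1_predictors", frozenset(self.loop1_predictors))
        object.__setattr__(self, "loop2_predictors", frozenset(self.loop2_predictors))
        if not self.loop1_predictors or not self.loop1_predictors <= KINEMATIC:
            raise ValueError("loop1_predictors must be a non-empty subset of {d, v, a}")
        if variant.is_single_loop:
            if self.loop2_predictors:
                raise ValueError(f"{variant.value} is single-loop; loop2 must be empty")
        elif variant is Variant.HSRM_KIN:
            if not self.loop2_predictors or not self.loop2_predictors <= KINEMATIC:
                raise ValueError("hSRM-kin loop2_predictors must be a non-empty subset of {d, v, a}")
        else:  # cortical-signal second loop
            if self.loop2_predictors != CORTICAL:
                raise ValueError(f"{variant.value} loop2 predictor must be the cortical signal")

    @classmethod
    def for_variant(
        cls,
        variant: Variant | str,
        accel_only_loop1: bool = False,
        accel_only_loop2: bool = False,
    ) -> "SRMSpec":
        variant = Variant(variant)
        loop1 = frozenset({"a"}) if accel_only_loop1 else KINEMATIC
        if variant.is_single_loop:
            loop2: FrozenSet[str] = frozenset()
        elif variant is Variant.HSRM_KIN:
            loop2 = frozenset({"a"}) if accel_only_loop2 else KINEMATIC
        else:
            loop2 = CORTICAL
        return cls(variant, loop1, loop2)

    @property
    def n_params(self) -> int:
        """Number of freely optimized parameters (each counted once)."""
        n = len(self.loop1_predictors) + 1  # gains + loop-1 delay
        if self.variant is Variant.HSRM_KIN:
            n += len(self.loop2_predictors) + 1
        elif self.variant.uses_cortical_predictor:
            n += 2  # cortical-signal gain + efferent delay
        return n

    @property
    def label(self) -> str:
        tags = []
        if self.loop1_predictors != KINEMATIC:
            tags.append("a1")
        if self.variant is Variant.HSRM_KIN and self.loop2_predictors != KINEMATIC:
            tags.append("a2")
        return self.variant.value + ("[" + ",".join(tags) + "]" if tags else "")


@dataclass(frozen=True)
class FeedbackGains:
    """Kinematic feedback gains (units reciprocal to the CoM channels)."""

    k_d: float = 0.0
    k_v: float = 0.0
    k_a: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_d", "k_v", "k_a"):
            val = float(getattr(self, name))
            if not np.isfinite(val):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, val)

    def as_array(self) -> np.ndarray:
        return np.array([self.k_d, self.k_v, self.k_a])

    def masked(self, predictors: FrozenSet[str]) -> "FeedbackGains":
        """Zero out gains for inactive predictors."""
        return FeedbackGains(
            self.k_d if "d" in predictors else 0.0,
            self.k_v if "v" in predictors else 0.0,
            self.k_a if "a" in predictors else 0.0,
        )

    @classmethod
    def from_mapping(cls, m) -> "FeedbackGains":
        return cls(m.get("k_d", 0.0), m.get("k_v", 0.0), m.get("k_a", 0.0))


@dataclass(frozen=True)
class LoopTiming:
    """Loop delays in ms.

    lambda_bs : subcortical loop delay (afferent + efferent).
    lambda_c  : cortical loop delay; must be >= lambda_bs when set.
    tau_c     : afferent delay to cortex; the efferent (cortex-to-muscle)
                delay is delta_c = lambda_c - tau_c >= 0.
    """

    lambda_bs: float = 0.0
    lambda_c: Optional[float] = None
    tau_c: Optional[float] = None
    delta_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lambda_bs < 0:
            raise ValueError("lambda_bs must be >= 0")
        if self.lambda_c is not None:
            if self.lambda_c < 0 or self.lambda_c < self.lambda_bs:
                raise ValueError("lambda_c must satisfy 0 <= lambda_bs <= lambda_c")
        if self.tau_c is not None and self.tau_c < 0:
            raise ValueError("tau_c must be >= 0")
        if self.delta_c is None and self.lambda_c is not None and self.tau_c is not None:
            object.__setattr__(self, "delta_c", self.lambda_c - self.tau_c)
        if self.delta_c is not None and self.delta_c < -1e-12:
            raise ValueError("efferent delay delta_c = lambda_c - tau_c must be >= 0")


@dataclass(frozen=True)
class SRMParams:
    """Full parameter set of one SRM variant."""

    spec: SRMSpec
    gains1: FeedbackGains
    timing: LoopTiming
    gains2: Optional[FeedbackGains] = None
    k_signal: Optional[float] = None

    def to_dict(self) -> dict:
        out = {
            "variant": self.spec.variant.value,
            "loop1_predictors": sorted(self.spec.loop1_predictors),
            "loop2_predictors": sorted(self.spec.loop2_predictors),
            "gains1": {"k_d": self.gains1.k_d, "k_v": self.gains1.k_v, "k_a": self.gains1.k_a},
            "lambda_bs": self.timing.lambda_bs,
            "lambda_c": self.timing.lambda_c,
            "tau_c": self.timing.tau_c,
            "delta_c": self.timing.delta_c,
        }
        if self.gains2 is not None:
            out["gains2"] = {"k_d": self.gains2.k_d, "k_v": self.gains2.k_v, "k_a": self.gains2.k_a}
        if self.k_signal is not None:
            out["k_signal"] = self.k_signal
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SRMParams":
        spec = SRMSpec(
            Variant(d["variant"]),
            frozenset(d.get("loop1_predictors", KINEMATIC)),
            frozenset(d.get("loop2_predictors", [])),
        )
        gains2 = FeedbackGains.from_mapping(d["gains2"]) if "gains2" in d else None
        return cls(
            spec,
            FeedbackGains.from_mapping(d["gains1"]),
            LoopTiming(
                d.get("lambda_bs", 0.0), d.get("lambda_c"), d.get("tau_c"), d.get("delta_c")
            ),
            gains2=gains2,
            k_signal=d.get("k_signal"),
        )

    def gain_vector(self) -> np.ndarray:
        """All active gains, in loop-1 (d, v, a) then loop-2 order."""
        parts = [getattr(self.gains1, f"k_{p}") for p in sorted(self.spec.loop1_predictors)]
        if self.gains2 is not None:
            parts += [getattr(self.gains2, f"k_{p}") for p in sorted(self.spec.loop2_predictors)]
        if self.k_signal is not None:
            parts.append(self.k_signal)
        return np.array(parts)


def rectify(x: np.ndarray) -> np.ndarray:
    """Half-wave rectification max(0, .): net excitatory drive to motor pools."""
    return np.maximum(0.0, x)


def _weighted_sum(com: ComKinematics, gains: FeedbackGains) -> np.ndarray:
    return gains.k_d * com.d.values + gains.k_v * com.v.values + gains.k_a * com.a.values


def _loop(com: ComKinematics, gains: FeedbackGains, delay_ms: float) -> np.ndarray:
    # weighting commutes with the common delay, so shift the summed signal once
    summed = com.d.with_values(_weighted_sum(com, gains))
    return delay_shift(summed, delay_ms).values


def reconstruct_msrm(
    com: ComKinematics, gains: FeedbackGains, timing: LoopTiming
) -> TimeSeries:
    """Single-loop muscle SRM: rectified, delayed kinematic feedback sum."""
    pre = _loop(com, gains, timing.lambda_bs)
    return com.d.with_values(rectify(pre))


def reconstruct_hsrm_kin(
    com: ComKinematics,
    gains1: FeedbackGains,
    gains2: FeedbackGains,
    timing: LoopTiming,
) -> TimeSeries:
    """Two-loop hierarchical SRM with a kinematic second loop at delay lambda_c."""
    if timing.lambda_c is None:
        raise ValueError("hSRM-kin requires lambda_c")
    pre = _loop(com, gains1, timing.lambda_bs) + _loop(com, gains2, timing.lambda_c)
    return com.d.with_values(rectify(pre))


def reconstruct_hsrm_cortical(
    com: ComKinematics,
    gains1: FeedbackGains,
    cortical: TimeSeries,
    k_signal: float,
    timing: LoopTiming,
) -> TimeSeries:
    """Hierarchical SRM whose second loop feeds a measured cortical signal.

    The cortical trace (resampled to the kinematic grid) is scaled by a
    sign-free gain and delayed by the efferent delay delta_c = lambda_c - tau_c.
    """
    if not cortical.same_grid(com.d):
        raise ValueError("cortical signal must be resampled to the kinematic grid")
    delta = timing.delta_c
    if delta is None:
        raise ValueError("cortical-signal loop requires delta_c (or lambda_c and tau_c)")
    pre = _loop(com, gains1, timing.lambda_bs) + k_signal * delay_shift(cortical, delta).values
    return com.d.with_values(rectify(pre))


def reconstruct_csrm(
    com: ComKinematics,
    gains: FeedbackGains,
    timing: LoopTiming,
    polarity: int = +1,
) -> TimeSeries:
    """Cortical SRM: kinematic feedback at the afferent delay tau_c.

    polarity -1 targets the negative-going Cz/N1 potential (the rectified
    reconstruction models the negated trace); +1 targets beta power.
    """
    if timing.tau_c is None:
        raise ValueError("cSRM requires tau_c")
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    pre = _loop(com, gains, timing.tau_c)
    return com.d.with_values(polarity * rectify(pre))


def reconstruct(
    params: SRMParams,
    com: ComKinematics,
    cortical: Optional[TimeSeries] = None,
) -> TimeSeries:
    """Dispatch the forward model for any variant."""
    spec = params.spec
    g1 = params.gains1.masked(spec.loop1_predictors)
    if spec.variant is Variant.MSRM:
        return reconstruct_msrm(com, g1, params.timing)
    if spec.variant is Variant.HSRM_KIN:
        if params.gains2 is None:
            raise ValueError("hSRM-kin requires gains2")
        return reconstruct_hsrm_kin(
            com, g1, params.gains2.masked(spec.loop2_predictors), params.timing
        )
    if spec.variant.uses_cortical_predictor:
        if cortical is None or params.k_signal is None:
            raise ValueError(f"{spec.variant.value} requires a cortical predictor and k_signal")
        return reconstruct_hsrm_cortical(com, g1, cortical, params.k_signal, params.timing)
    return reconstruct_csrm(com, g1, params.timing, polarity=spec.variant.polarity)
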