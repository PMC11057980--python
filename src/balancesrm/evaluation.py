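"""Goodness of fit and model selection.

R^2 is the coefficient of determination of an intercept-including ordinary
least-squares regression of the observed signal on the reconstruction
(equivalently, the squared centered Pearson correlation, so it is invariant
to affine transforms of the reconstruction). VAF is 100 x the squared
*uncentered* Pearson correlation, invariant to positive rescaling but not to
offsets. Model selection uses AIC = N log(SSR/N) + 2 P, summed across fits,
with a difference of at least 2 required to prefer one variant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .fitting import SRMFit
from .timeseries import TimeSeries

__all__ = [
    "FitMetrics",
    "ModelComparison",
    "r_squared",
    "vaf",
    "aic",
    "metrics_for_fit",
    "compare_models",
]

AIC_MEANINGFUL = 2.0


def _as_array(x) -> np.ndarray:
    if isinstance(x, TimeSeries):
        return x.values
    return np.asarray(x, dtype=float)


def r_squared(observed, reconstruction) -> float:
    """Squared centered Pearson correlation; NaN if either side is constant."""
    o = _as_array(observed)
    r = _as_array(reconstruction)
    if o.shape != r.shape:
        raise ValueError("signals must have equal length")
    oc = o - o.mean()
    rc = r - r.mean()
    denom = float(oc @ oc) * float(rc @ rc)
    if denom <= 0:
        return float("nan")
    return float((oc @ rc) ** 2 / denom)


def vaf(observed, reconstruction) -> float:
    """Variance accounted for: 100 x squared uncentered correlation."""
    o = _as_array(observed)
    r = _as_array(reconstruction)
    if o.shape != r.shape:
        raise ValueError("signals must have equal length")
    denom = float(o @ o) * float(r @ r)
    if denom <= 0:
        return float("nan")
    return float(100.0 * (o @ r) ** 2 / denom)


def aic(ssr: float, n_data: int, n_params: int) -> float:
    """Akaike information criterion: N log(SSR/N) + 2 P (natural log)."""
    if n_data < 1 or n_params < 1:
        raise ValueError("n_data and n_params must be >= 1")
    if ssr < 0:
        raise ValueError("SSR must be non-negative")
    if ssr == 0.0:
        warnings.warn("SSR is exactly zero; AIC is -inf", RuntimeWarning, stacklevel=2)
        return float("-inf")
    return float(n_data * math.log(ssr / n_data) + 2 * n_params)


@dataclass(frozen=True)
class FitMetrics:
    """Per-fit goodness-of-fit summary."""

    r2: float
    vaf: float
    aic: float
    ssr: float
    n_data: int
    n_params: int

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "vaf": self.vaf,
            "aic": self.aic,
            "ssr": self.ssr,
            "n_data": self.n_data,
            "n_params": self.n_params,
        }


def metrics_for_fit(fit: SRMFit, observed: Optional[TimeSeries] = None) -> FitMetrics:
    """Compute R^2, VAF and AIC for a fitted SRM on its fit window."""
    obs = observed if observed is not None else fit.reconstruction.with_values(
        fit.reconstruction.values + fit.residual.values
    )
    mask = obs.window_mask(fit.window.t_start, fit.window.t_end)
    o = obs.values[mask]
    r = fit.reconstruction.values[mask]
    return FitMetrics(
        r2=r_squared(o, r),
        vaf=vaf(o, r),
        aic=aic(fit.ssr, fit.n_data, fit.n_params) if fit.ssr > 0 else float("-inf"),
        ssr=fit.ssr,
        n_data=fit.n_data,
        n_params=fit.n_params,
    )


@dataclass(frozen=True)
class ModelComparison:
    """Summed-AIC comparison across SRM variants fitted to the same trials."""

    total_aic: Dict[str, float]
    best: str
    delta_aic: Dict[str, float]
    preferred: Optional[str]

    def summary(self) -> str:
        lines = [f"{'variant':<16}{'sum AIC':>14}{'dAIC':>10}"]
        for name in sorted(self.total_aic, key=self.total_aic.get):
            mark = "  *" if name == self.preferred else ""
            lines.append(
                f"{name:<16}{self.total_aic[name]:>14.2f}{self.delta_aic[name]:>10.2f}{mark}"
            )
        if self.preferred is None:
            lines.append("no variant preferred (dAIC < 2)")
        return "\n".join(lines)


def compare_models(
    fits_by_variant: Mapping[str, Sequence[SRMFit]],
    keys_by_variant: Optional[Mapping[str, Sequence]] = None,
) -> ModelComparison:
    """Sum per-fit AIC within each variant and compare.

    Every variant must be fitted on the same set of trials; optionally pass
    per-variant trial keys to enforce that the sets match. The lowest summed
    AIC wins, but a preference is declared only when the margin over the
    runner-up is at least 2.
    """
    if not fits_by_variant:
        raise ValueError("no fits to compare")
    counts = {v: len(f) for v, f in fits_by_variant.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"unequal trial counts across variants: {counts}")
    if keys_by_variant is not None:
        key_sets = {v: tuple(sorted(map(str, k))) for v, k in keys_by_variant.items()}
        if len(set(key_sets.values())) != 1:
            raise ValueError("variants were fitted on different trial sets")
    total = {
        v: float(sum(aic(f.ssr, f.n_data, f.n_params) for f in fits))
        for v, fits in fits_by_variant.items()
    }
    best = min(sorted(total), key=total.get)
    delta = {v: total[v] - total[best] for v in total}
    runner_up = min((d for v, d in delta.items() if v != best), default=float("inf"))
    preferred = best if runner_up >= AIC_MEANINGFUL else None
    return ModelComparison(total, best, delta, preferred)
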