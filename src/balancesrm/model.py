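"""Model / Results interface over the SRM fitting machinery.

`SensorimotorResponseModel` is constructed from data (the observed trace and
the CoM balance-error kinematics), `fit()` runs the variant-appropriate
optimization and returns an `SRMResults` carrying the estimates, diagnostics
and a text `summary()`; `simulate()` evaluates the forward model for any
parameter set, and `SRMResults.plot()` overlays observation and
reconstruction.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .evaluation import FitMetrics, metrics_for_fit
from .fitting import FitConfig, SRMFit, fit_srm
from .forward import SRMParams, SRMSpec, Variant, reconstruct
from .timeseries import ComKinematics, TimeSeries

__all__ = ["SensorimotorResponseModel", "SRMResults"]


class SensorimotorResponseModel:
    """A sensorimotor response model bound to one observed trace.

    Parameters
    ----------
    observed : TimeSeries
        Condition-averaged target trace (EMG envelope, Cz epoch or beta
        power) on the common analysis grid.
    com : ComKinematics
        CoM displacement / velocity / acceleration balance-error signals on
        the same grid.
    variant : Variant, str or SRMSpec
        Which SRM to fit; a plain variant name uses the full predictor sets.
    cortical : TimeSeries, optional
        Measured cortical predictor (required for hSRM-N1 / hSRM-beta).
    """

    def __init__(
        self,
        observed: TimeSeries,
        com: ComKinematics,
        variant: Variant | str | SRMSpec = Variant.MSRM,
        cortical: Optional[TimeSeries] = None,
    ):
        self.spec = variant if isinstance(variant, SRMSpec) else SRMSpec.for_variant(variant)
        if not observed.same_grid(com.d):
            raise ValueError("observed trace and kinematics must share a grid")
        if self.spec.variant.uses_cortical_predictor:
            if cortical is None:
                raise ValueError(f"{self.spec.variant.value} needs a cortical predictor trace")
            if not cortical.same_grid(com.d):
                raise ValueError("cortical predictor must share the analysis grid")
        self.observed = observed
        self.com = com
        self.cortical = cortical

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        fs: float,
        variant: Variant | str | SRMSpec = Variant.MSRM,
        observed_col: str = "emg",
        time_col: str = "time_ms",
        cortical_col: Optional[str] = None,
    ) -> "SensorimotorResponseModel":
        """Build a model from a tidy frame with time, target and com_d/v/a columns."""
        t0 = float(df[time_col].iloc[0])
        mk = lambda col: TimeSeries(df[col].to_numpy(dtype=float), fs, t0)
        com = ComKinematics(mk("com_d"), mk("com_v"), mk("com_a"))
        cortical = mk(cortical_col) if cortical_col else None
        return cls(mk(observed_col), com, variant, cortical=cortical)

    def fit(self, config: Optional[FitConfig] = None) -> "SRMResults":
        """Identify gains and delays by penalized constrained optimization."""
        cfg = config or FitConfig()
        fit = fit_srm(self.observed, self.com, self.spec, cfg, cortical=self.cortical)
        return SRMResults(self, fit, cfg)

    def simulate(self, params: SRMParams) -> TimeSeries:
        """Forward-reconstruct the target trace for a given parameter set."""
        return reconstruct(params, self.com, cortical=self.cortical)


class SRMResults:
    """Fitted SRM: parameter estimates, objective diagnostics and metrics."""

    def __init__(self, model: SensorimotorResponseModel, fit: SRMFit, config: FitConfig):
        self.model = model
        self.fit = fit
        self.config = config
        self._metrics: Optional[FitMetrics] = None

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> SRMParams:
        return self.fit.params

    @property
    def cost(self) -> float:
        return self.fit.cost

    @property
    def ssr(self) -> float:
        return self.fit.ssr

    @property
    def reconstruction(self) -> TimeSeries:
        return self.fit.reconstruction

    @property
    def residual(self) -> TimeSeries:
        return self.fit.residual

    @property
    def metrics(self) -> FitMetrics:
        if self._metrics is None:
            self._metrics = metrics_for_fit(self.fit, observed=self.model.observed)
        return self._metrics

    @property
    def rsquared(self) -> float:
        return self.metrics.r2

    @property
    def vaf(self) -> float:
        return self.metrics.vaf

    @property
    def aic(self) -> float:
        return self.metrics.aic

    def params_frame(self) -> pd.DataFrame:
        """Estimates as a one-row DataFrame (NaN for inactive parameters)."""
        d = self.params.to_dict()
        row = {
            "variant": self.params.spec.label,
            "k_d1": d["gains1"]["k_d"],
            "k_v1": d["gains1"]["k_v"],
            "k_a1": d["gains1"]["k_a"],
            "lambda_bs": d["lambda_bs"],
            "lambda_c": d.get("lambda_c"),
            "tau_c": d.get("tau_c"),
            "delta_c": d.get("delta_c"),
            "k_signal": d.get("k_signal"),
        }
        if "gains2" in d:
            row.update(
                k_d2=d["gains2"]["k_d"], k_v2=d["gains2"]["k_v"], k_a2=d["gains2"]["k_a"]
            )
        return pd.DataFrame([row])

    def to_dict(self) -> dict:
        m = self.metrics
        return {
            "params": self.params.to_dict(),
            "cost": self.cost,
            "ssr": self.ssr,
            "metrics": m.to_dict(),
            "window": [self.fit.window.t_start, self.fit.window.t_end],
            "n_data": self.fit.n_data,
            "n_params": self.fit.n_params,
            "flags": list(self.fit.flags),
            "stage_costs": list(self.fit.stage_costs),
        }

    def summary(self) -> str:
        """Plain-text estimation summary."""
        p = self.params
        m = self.metrics
        spec = p.spec
        lines = [
            "Sensorimotor Response Model Results",
            "=" * 45,
            f"variant:        {spec.label}",
            f"n_data:         {self.fit.n_data}",
            f"n_params:       {self.fit.n_params}",
            f"fit window:     {self.fit.window.t_start:.0f}..{self.fit.window.t_end:.0f} ms",
            f"objective cost: {self.cost:.6g}",
            f"SSR:            {self.ssr:.6g}",
            f"R^2:            {m.r2:.4f}",
            f"VAF:            {m.vaf:.2f} %",
            f"AIC:            {m.aic:.2f}",
            "-" * 45,
        ]
        for name in sorted(spec.loop1_predictors):
            lines.append(f"k_{name}1      = {getattr(p.gains1, f'k_{name}'):.6g}")
        if spec.variant.is_cortical_target:
            lines.append(f"tau_c     = {p.timing.tau_c:.2f} ms")
        else:
            lines.append(f"lambda_bs = {p.timing.lambda_bs:.2f} ms")
        if p.gains2 is not None:
            for name in sorted(spec.loop2_predictors):
                lines.append(f"k_{name}2      = {getattr(p.gains2, f'k_{name}'):.6g}")
            lines.append(f"lambda_c  = {p.timing.lambda_c:.2f} ms")
        if p.k_signal is not None:
            lines.append(f"k_signal  = {p.k_signal:.6g}")
            lines.append(f"delta_c   = {p.timing.delta_c:.2f} ms")
        if self.fit.flags:
            lines.append("flags: " + "; ".join(self.fit.flags))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed vs reconstructed trace over the fit window."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 3))
        t = self.model.observed.times
        ax.plot(t, self.model.observed.values, color="0.4", lw=1.0, label="observed")
        ax.plot(t, self.reconstruction.values, color="crimson", lw=1.2, label="reconstruction")
        ax.axvspan(self.fit.window.t_start, self.fit.window.t_end, color="0.92", zorder=0)
        ax.set_xlabel("time from perturbation onset (ms)")
        ax.set_ylabel("amplitude")
        ax.set_title(self.params.spec.label)
        ax.legend(frameon=False)
        return ax
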