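"""End-to-end analysis pipeline: simulate -> preprocess -> fit -> evaluate -> compare.

A validated `RunConfig` (YAML-serialisable) drives every stage; re-running
the same config reproduces the results bundle byte for byte. Per-fit results
are written as JSON, the variant comparison as CSV plus a Markdown report,
and a run log records the config hash and seeds (no wall-clock content, so
bundles stay deterministic).
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import preprocessing as prep
from .evaluation import compare_models
from .fitting import FitConfig, FitWindow, ObjectiveWeights
from .forward import SRMSpec, Variant
from .io import write_json, write_timeseries
from .model import SensorimotorResponseModel
from .synthetic import (
    MAGNITUDES,
    NoiseModel,
    PlantParams,
    SyntheticTrial,
    generate_dataset,
)
from .timeseries import ComKinematics, TimeSeries

__all__ = ["RunConfig", "run_pipeline", "VARIANT_LABELS", "bundle_hash", "demo_config"]

log = logging.getLogger("balancesrm")

# config label -> (spec factory kwargs, target trace)
VARIANT_LABELS: Dict[str, Tuple[SRMSpec, str]] = {
    "mSRM": (SRMSpec.for_variant(Variant.MSRM), "emg"),
    "hSRM-kin": (SRMSpec.for_variant(Variant.HSRM_KIN), "emg"),
    "hSRM-kin-a2": (SRMSpec.for_variant(Variant.HSRM_KIN, accel_only_loop2=True), "emg"),
    "hSRM-N1": (SRMSpec.for_variant(Variant.HSRM_N1), "emg"),
    "hSRM-beta": (SRMSpec.for_variant(Variant.HSRM_BETA), "emg"),
    "cSRM-N1": (SRMSpec.for_variant(Variant.CSRM_N1), "cz"),
    "cSRM-N1-a1": (SRMSpec.for_variant(Variant.CSRM_N1, accel_only_loop1=True), "cz"),
    "cSRM-beta": (SRMSpec.for_variant(Variant.CSRM_BETA), "beta"),
    "cSRM-beta-a1": (SRMSpec.for_variant(Variant.CSRM_BETA, accel_only_loop1=True), "beta"),
}


class NoiseConfig(BaseModel, extra="forbid"):
    sigma0: float = 0.01
    sigma_prop: float = 0.05


class PlantConfig(BaseModel, extra="forbid"):
    effective_stiffness: float = 20.0
    damping: float = 6.0


class FitSettings(BaseModel, extra="forbid"):
    window: Tuple[float, float] = (0.0, 1300.0)
    mu_s: float = 1000.0  # seconds-scale equivalent of a sample-summed e^2 term
    mu_m: float = 1.0
    mu_k: float = 1e-6
    n_starts: int = 3

    def to_fit_config(self) -> FitConfig:
        return FitConfig(
            weights=ObjectiveWeights(self.mu_s, self.mu_m, self.mu_k),
            window=FitWindow(*self.window),
            n_starts=self.n_starts,
        )


class RunConfig(BaseModel, extra="forbid"):
    """Validated run configuration; defaults mirror the study protocol."""

    seed: int = 0
    n_participants: int = 17
    magnitudes: List[str] = Field(default_factory=lambda: list(MAGNITUDES))
    trials_per_cell: int = 8
    generator_variant: str = "hSRM-kin-a2"
    noise: NoiseConfig = NoiseConfig()
    plant: PlantConfig = PlantConfig()
    fs: float = 1000.0
    epoch: Tuple[float, float] = (-400.0, 1400.0)
    emg_is_envelope: bool = True
    variants: List[str] = Field(default_factory=lambda: list(VARIANT_LABELS))
    fit: FitSettings = FitSettings()
    emg_bins: List[Tuple[float, float]] = Field(default_factory=lambda: list(prep.EMG_BINS))
    beta_bins: List[Tuple[float, float]] = Field(default_factory=lambda: list(prep.BETA_BINS))
    write_trials: bool = False
    log_level: str = "INFO"

    @field_validator("variants", "generator_variant")
    @classmethod
    def _known_variants(cls, v):
        names = [v] if isinstance(v, str) else v
        unknown = [n for n in names if n not in VARIANT_LABELS]
        if unknown:
            raise ValueError(f"unknown variant name(s): {unknown}; known: {list(VARIANT_LABELS)}")
        return v

    @field_validator("magnitudes")
    @classmethod
    def _known_magnitudes(cls, v):
        unknown = [m for m in v if m not in MAGNITUDES]
        if unknown:
            raise ValueError(f"unknown magnitude label(s): {unknown}")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def demo_config(n_participants: int = 3, trials_per_cell: int = 2) -> RunConfig:
    """Small three-participant demo covering every model variant."""
    return RunConfig(n_participants=n_participants, trials_per_cell=trials_per_cell)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _average(traces: Sequence[TimeSeries]) -> TimeSeries:
    stacked = np.stack([t.values for t in traces])
    return traces[0].with_values(stacked.mean(axis=0))


def simulate_stage(config: RunConfig, out_dir: Path) -> Tuple[List[SyntheticTrial], Dict]:
    gen_spec, _ = VARIANT_LABELS[config.generator_variant]
    trials, manifest = generate_dataset(
        n_participants=config.n_participants,
        magnitudes=config.magnitudes,
        trials_per_cell=config.trials_per_cell,
        base_seed=config.seed,
        muscle_variant=gen_spec.variant,
        accel_only_loop2=(gen_spec.loop2_predictors == frozenset({"a"})),
        noise=NoiseModel(config.noise.sigma0, config.noise.sigma_prop),
        plant=PlantParams(config.plant.effective_stiffness, config.plant.damping),
        fs=config.fs,
        epoch=config.epoch,
    )
    write_json(manifest, out_dir / "manifest.json")
    if config.write_trials:
        for i, tr in enumerate(trials):
            stem = out_dir / "trials" / f"{tr.participant}_{tr.magnitude}_{i:03d}"
            for name in ("emg", "cz", "beta"):
                write_timeseries(getattr(tr, name), f"{stem}_{name}.csv")
            for name in ("d", "v", "a"):
                write_timeseries(getattr(tr.com, name), f"{stem}_com-{name}.csv")
    log.info("simulate: %d trials (%d participants x %s x %d)",
             len(trials), config.n_participants, config.magnitudes, config.trials_per_cell)
    return trials, manifest


def preprocess_stage(
    config: RunConfig, trials: Sequence[SyntheticTrial], out_dir: Path
) -> Dict[Tuple[str, str], Dict]:
    """Envelope conditioning, per-participant normalization, condition averages."""
    by_participant: Dict[str, List[SyntheticTrial]] = defaultdict(list)
    for tr in trials:
        by_participant[tr.participant].append(tr)
    cells: Dict[Tuple[str, str], Dict] = {}
    for pid in sorted(by_participant):
        ptrials = by_participant[pid]
        envs = [tr.emg if config.emg_is_envelope else prep.process_emg(tr.emg) for tr in ptrials]
        envs = prep.normalize_emg(envs, groups=[pid] * len(envs))
        for mag in config.magnitudes:
            idx = [i for i, tr in enumerate(ptrials) if tr.magnitude == mag]
            if not idx:
                continue
            emg_avg = _average([envs[i] for i in idx])
            cz_avg = _average([ptrials[i].cz for i in idx])
            beta_avg = _average([ptrials[i].beta for i in idx])
            cell = {
                "emg": emg_avg,
                "cz": cz_avg,
                "beta": beta_avg,
                "com": ptrials[idx[0]].com,
                "emg_bins": prep.integrate_bins(emg_avg, config.emg_bins),
                "n1": prep.n1_features(cz_avg),
            }
            cells[(pid, mag)] = cell
            stem = out_dir / "averages" / f"{pid}_{mag}"
            for name in ("emg", "cz", "beta"):
                write_timeseries(cell[name], f"{stem}_{name}.csv")
    log.info("preprocess: %d condition-averaged cells", len(cells))
    return cells


def fit_stage(
    config: RunConfig, cells: Dict[Tuple[str, str], Dict], out_dir: Path
) -> Dict[str, Dict[Tuple[str, str], "object"]]:
    fit_cfg = config.fit.to_fit_config()
    results: Dict[str, Dict[Tuple[str, str], object]] = defaultdict(dict)
    for (pid, mag), cell in sorted(cells.items()):
        for name in config.variants:
            spec, target = VARIANT_LABELS[name]
            cortical = None
            if spec.variant.uses_cortical_predictor:
                cortical = cell["cz"] if spec.variant is Variant.HSRM_N1 else cell["beta"]
            model = SensorimotorResponseModel(cell[target], cell["com"], spec, cortical=cortical)
            res = model.fit(fit_cfg)
            results[name][(pid, mag)] = res
            payload = res.to_dict()
            payload.update(participant=pid, magnitude=mag, variant=name, target=target)
            payload["n1"] = {
                "amplitude_uv": cell["n1"].n1_amplitude,
                "latency_ms": cell["n1"].n1_latency,
            }
            payload["emg_bins"] = {
                f"{int(a)}-{int(b)}ms": v
                for (a, b), v in zip(cell["emg_bins"].bin_edges, cell["emg_bins"].values)
            }
            write_json(payload, out_dir / "fits" / f"{pid}_{mag}_{name}.json")
        log.info("fit: %s %s done (%d variants)", pid, mag, len(config.variants))
    return results


def compare_stage(
    config: RunConfig, results: Dict[str, Dict[Tuple[str, str], object]], out_dir: Path
) -> Dict[str, object]:
    groups: Dict[str, List[str]] = defaultdict(list)
    for name in config.variants:
        groups[VARIANT_LABELS[name][1]].append(name)
    comparisons = {}
    report = ["# Model comparison (summed AIC per target)", ""]
    rows = ["target,variant,total_aic,delta_aic,preferred"]
    for target in sorted(groups):
        names = groups[target]
        if len(names) < 2:
            continue
        fits = {n: [results[n][k].fit for k in sorted(results[n])] for n in names}
        keys = {n: [f"{k}" for k in sorted(results[n])] for n in names}
        comp = compare_models(fits, keys)
        comparisons[target] = comp
        report += [f"## target: {target}", "", "```", comp.summary(), "```", ""]
        for n in names:
            rows.append(
                f"{target},{n},{comp.total_aic[n]!r},{comp.delta_aic[n]!r},"
                f"{int(n == comp.preferred)}"
            )
    (out_dir / "comparison.csv").write_text("\n".join(rows) + "\n")
    (out_dir / "report.md").write_text("\n".join(report))
    flagged = [
        f"{n} {k}: {'; '.join(results[n][k].fit.flags)}"
        for n in results
        for k in sorted(results[n])
        if results[n][k].fit.flags
    ]
    if flagged:
        (out_dir / "warnings.txt").write_text("\n".join(sorted(flagged)) + "\n")
    log.info("compare: %d target groups", len(comparisons))
    return comparisons


def run_pipeline(config: RunConfig, out_dir) -> Dict[str, object]:
    """Execute all stages and write the results bundle under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.to_yaml(out_dir / "config.yaml")
    stage = "simulate"
    try:
        trials, manifest = simulate_stage(config, out_dir)
        stage = "preprocess"
        cells = preprocess_stage(config, trials, out_dir)
        stage = "fit"
        results = fit_stage(config, cells, out_dir)
        stage = "compare"
        comparisons = compare_stage(config, results, out_dir)
    except Exception as exc:  # surface which stage died
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    (out_dir / "run_log.txt").write_text(
        "\n".join(
            [
                f"config_hash: {config.config_hash()}",
                f"seed: {config.seed}",
                f"trials: {len(trials)}",
                f"cells: {len(cells)}",
                f"variants: {','.join(config.variants)}",
            ]
        )
        + "\n"
    )
    return {"results": results, "comparisons": comparisons, "manifest": manifest}


def bundle_hash(out_dir) -> str:
    """SHA-256 over every file in a results bundle (sorted relative paths)."""
    out_dir = Path(out_dir)
    h = hashlib.sha256()
    for path in sorted(p for p in out_dir.rglob("*") if p.is_file()):
        h.update(str(path.relative_to(out_dir)).encode())
        h.update(path.read_bytes())
    return h.hexdigest()
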