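"""Trace/manifest/result I/O.

Traces are two-column CSV (``time_s``, ``current_A``) with an optional
JSON sidecar (same path + ``.meta.json``) for condition metadata.
Experiment manifests are YAML validated through pydantic; results are
JSON documents that round-trip losslessly.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from timeskit import __version__ as _pkg_version
from timeskit.inference import Condition, ExperimentSet, InferenceResult
from timeskit.model_core import ChannelGeometry, parse_concentration
from timeskit.surface_signal import SignalTrace

UNIFORM_GRID_RTOL = 1e-6


def write_trace(trace: SignalTrace, path: str | Path) -> None:
    """Write a trace as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.t, "current_A": trace.current})
    # 18 significant digits: float64 round-trips exactly through text
    df.to_csv(path, index=False, float_format="%.17e")
    meta = {k: v for k, v in trace.meta.items()}
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, default=float)


def read_trace(path: str | Path) -> SignalTrace:
    """Read a two-column CSV trace, validating grid uniformity and finiteness."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "current_A"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    i = df["current_A"].to_numpy(dtype=float)
    bad = np.nonzero(~(np.isfinite(t) & np.isfinite(i)))[0]
    if len(bad):
        raise ValueError(f"{path}: non-finite values at rows {bad[:10].tolist()}"
                         f" (2-based including header: {(bad + 2)[:10].tolist()})")
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError(f"{path}: a trace needs at least two rows")
    dev = np.abs(dt - dt[0])
    worst = int(np.argmax(dev))
    if dev[worst] > UNIFORM_GRID_RTOL * abs(dt[0]):
        raise ValueError(
            f"{path}: non-uniform time grid at row {worst + 2} "
            f"(Δt={dt[worst]:.9g} vs {dt[0]:.9g})")
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SignalTrace(t=t, current=i, meta=meta)


class GeometryModel(BaseModel):
    half_height_m: float = 15e-6
    width_m: float = 0.5e-3
    electrode_area_m2: float = 1e-6
    buffer_viscosity_pa_s: float = 1.0e-3
    temperature_k: float = 298.15
    zeta_potential_v: float = -0.025
    ionic_strength_mol_m3: float = 5.0

    def to_geometry(self) -> ChannelGeometry:
        return ChannelGeometry(
            half_height=self.half_height_m, width=self.width_m,
            electrode_area=self.electrode_area_m2,
            buffer_viscosity=self.buffer_viscosity_pa_s,
            temperature=self.temperature_k,
            zeta_potential=self.zeta_potential_v,
            ionic_strength=self.ionic_strength_mol_m3)


class ConditionModel(BaseModel):
    protein: str | float = Field(description="initial protein concentration, e.g. '100 uM'")
    ligand: str | float = Field(description="initial ligand concentration")
    flow_rate_m3_s: float = 5e-10
    trace: str

    @field_validator("protein", "ligand")
    @classmethod
    def _parseable(cls, v):
        parse_concentration(v)
        return v


class AnalysisModel(BaseModel):
    window_start_s: float | None = None
    c_tau: float = 0.5
    n_bins: int = 50
    bracket_mol_m3: tuple[float, float] = (1e-9, 1e1)
    n_scan: int = 64
    regularization: float = 1e-3


class ExperimentManifest(BaseModel):
    """Schema-validated description of a multi-condition experiment."""

    schema_version: int = 1
    name: str = "experiment"
    seed: int = 0
    diffusion_time_s: float | None = None
    geometry: GeometryModel = GeometryModel()
    conditions: list[ConditionModel]
    analysis: AnalysisModel = AnalysisModel()


def read_manifest(path: str | Path) -> ExperimentManifest:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ExperimentManifest.model_validate(data)


def write_manifest(manifest: ExperimentManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(manifest.model_dump_json()), fh,
                       sort_keys=False)


def load_experiment(manifest: ExperimentManifest,
                    base_dir: str | Path = ".") -> ExperimentSet:
    """Materialise an ExperimentSet from a manifest, reading every trace."""
    base = Path(base_dir)
    conditions = []
    for c in manifest.conditions:
        tr_path = base / c.trace
        if not tr_path.exists():
            raise FileNotFoundError(f"trace file not found: {tr_path}")
        trace = read_trace(tr_path)
        conditions.append(Condition(
            x=parse_concentration(c.protein),
            y=parse_concentration(c.ligand),
            flow_rate=c.flow_rate_m3_s,
            trace=trace))
    meta: dict[str, Any] = {"name": manifest.name, "seed": manifest.seed}
    if manifest.diffusion_time_s is not None:
        meta["diffusion_time"] = manifest.diffusion_time_s
    return ExperimentSet(conditions=conditions,
                         geometry=manifest.geometry.to_geometry(),
                         meta=meta)


def manifest_hash(manifest: ExperimentManifest) -> str:
    return hashlib.sha256(manifest.model_dump_json().encode()).hexdigest()[:16]


def result_document(result: InferenceResult, manifest: ExperimentManifest | None = None,
                    replicate_mean: float | None = None,
                    replicate_sd: float | None = None) -> dict:
    """Serializable result with provenance (config hash, seed, version)."""
    doc = {
        "kd_mode_mol_m3": result.kd_mode,
        "kd_mean_of_modal_bin_mol_m3": result.kd_mean_of_modal_bin,
        "kd_modal_bin_center_mol_m3": result.kd_modal_bin_center,
        "histogram": {
            "edges_mol_m3": result.histogram_edges.tolist(),
            "counts": result.histogram_counts.tolist(),
        },
        "kd_samples_mol_m3": [None if not np.isfinite(v) else float(v)
                              for v in result.kd_samples],
        "tau_s": result.tau_s,
        "diagnostics": result.diagnostics,
        "provenance": {
            "software_version": _pkg_version,
        },
    }
    if replicate_mean is not None:
        doc["kd_replicates_mol_m3"] = {"mean": replicate_mean, "sd": replicate_sd}
    if manifest is not None:
        doc["provenance"]["manifest_hash"] = manifest_hash(manifest)
        doc["provenance"]["seed"] = manifest.seed
        doc["provenance"]["scenario"] = manifest.name
    return doc


def write_result(doc: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=float)


def read_result(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
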