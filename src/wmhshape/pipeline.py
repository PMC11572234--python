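"""End-to-end orchestration: simulate -> classify -> extract -> associate.

A :class:`RunConfig` selects stages and options; :func:`run_pipeline`
executes them in order and writes a JSON manifest recording the config, the
seed, per-stage counts and any warnings (skipped lesions, failed model
cells), so every number in the final report is traceable to a stage, a
config and a seed.  Identical config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, shape_markers, synthetic_data, wmh_typing
from .mask_model import VolumeGeometry, load_mask, mask_volume_ml, save_labels
from .synthetic_data import CohortSimConfig, LesionSpec, PhantomSpec

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "random_phantom", "phantom_cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "wmhshape_run"
    stages: tuple[str, ...] = ("simulate", "classify", "extract", "associate")
    n_participants: int = 20
    mean_lesions: float = 4.0
    connectivity: int = 26
    radii_mm: tuple[float, float] = wmh_typing.DEFAULT_RADII_MM
    surface_method: str = "marching_cubes"
    at_risk_only: bool = True
    invert_linear: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.radii_mm[0] < self.radii_mm[1]:
            raise ValueError("inflation radii must be strictly increasing")
        unknown = set(self.stages) - {"simulate", "classify", "extract", "associate"}
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "radii_mm" in data:
            data["radii_mm"] = tuple(data["radii_mm"])
        return cls(**data)


def random_phantom(seed: int, mean_lesions: float = 4.0,
                   geometry: VolumeGeometry | None = None) -> PhantomSpec:
    """Draw a participant phantom with a random lesion load.

    Lesion count is 1 + Poisson(mean-1); centers are uniform inside a safe
    margin, base radii log-normal around ~5 mm, irregularity kappa uniform
    on [0, 0.8].  Lesion type (periventricular/confluent vs deep) emerges
    from where the lesion lands relative to the ventricles.
    """
    base = PhantomSpec(seed=seed) if geometry is None else PhantomSpec(
        geometry=geometry, seed=seed
    )
    rng = np.random.default_rng(seed)
    extent = np.array(base.geometry.shape) * base.geometry.spacing
    n_lesions = 1 + rng.poisson(max(mean_lesions - 1.0, 0.0))
    lesions = []
    for j in range(int(n_lesions)):
        radii = np.exp(rng.normal(np.log(5.0), 0.3, 3))
        margin = radii.max() * 2.2 + 2.0
        center = rng.uniform(margin, extent - margin)
        lesions.append(
            LesionSpec(
                center_mm=tuple(center),
                semi_axes_mm=tuple(radii),
                kappa=float(rng.uniform(0.0, 0.8)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return dataclass_replace(base, lesions=tuple(lesions))


def dataclass_replace(spec: PhantomSpec, **kw) -> PhantomSpec:
    from dataclasses import replace

    return replace(spec, **kw)


def phantom_cohort(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Generate phantoms, type lesions and extract per-participant markers."""
    rng = np.random.default_rng(config.seed)
    rows = []
    counts = {"participants": 0, "lesions": 0, "skipped_components": 0}
    for i in range(config.n_participants):
        spec = random_phantom(
            seed=int(rng.integers(0, 2**31 - 1)), mean_lesions=config.mean_lesions
        )
        vent, wmh, truth = synthetic_data.make_participant_images(spec)
        labels, comps, typed = wmh_typing.type_wmh(
            wmh, vent, radii_mm=config.radii_mm, connectivity=config.connectivity
        )
        ms = shape_markers.participant_markers(
            typed, labels, surface_method=config.surface_method
        )
        row = {"id": f"S{i:04d}", **ms.as_dict()}
        row["age"] = float(rng.normal(74.5, 4.7))
        row["sex"] = int(rng.uniform() < 0.61)
        row["wmh_baseline_ml"] = mask_volume_ml(wmh)
        row["n_true_lesions"] = len(truth)
        rows.append(row)
        counts["participants"] += 1
        counts["lesions"] += len(comps)
        counts["skipped_components"] += ms.n_skipped
    return pd.DataFrame(rows), counts


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages; return (and write) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_dict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": [],
        "warnings": [],
    }

    cohort: pd.DataFrame | None = None

    if "simulate" in config.stages:
        imaging, counts = phantom_cohort(config)
        sim_cfg = CohortSimConfig(
            n=max(config.n_participants, 10), seed=config.seed
        )
        rng = np.random.default_rng(config.seed + 1)
        cohort = synthetic_data.simulate_outcomes(imaging, sim_cfg, rng)
        path = outdir / "cohort.csv"
        _write_csv(cohort, path)
        manifest["stages"].append(
            {"stage": "simulate", "rows": len(cohort), **counts, "output": path.name}
        )
        if counts["skipped_components"]:
            manifest["warnings"].append(
                f"skipped {counts['skipped_components']} sub-voxel-threshold lesion component(s)"
            )

    if "associate" in config.stages:
        if cohort is None:
            cohort_path = outdir / "cohort.csv"
            if not cohort_path.exists():
                raise FileNotFoundError(
                    f"associate stage needs {cohort_path}; run simulate first"
                )
            cohort = pd.read_csv(cohort_path)
        results, failures = _associate_with_fallback(cohort, config)
        res_df = association.results_to_frame(results)
        _write_csv(res_df, outdir / "associations.csv")
        table = association.build_results_table(results)
        (outdir / "results_table.md").write_text(table.to_markdown() + "\n")
        manifest["stages"].append(
            {
                "stage": "associate",
                "cells_fit": len(results),
                "cells_failed": len(failures),
                "output": "associations.csv",
            }
        )
        manifest["warnings"].extend(failures)

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _associate_with_fallback(cohort: pd.DataFrame, config: RunConfig):
    """Fit every grid cell, recording (not raising) per-cell failures."""
    df = association.derive_volumes(cohort)
    results, failures = [], []
    for pred in association.ALL_PREDICTORS:
        if pred not in df.columns:
            failures.append(f"predictor {pred} absent from cohort")
            continue
        try:
            results.append(association.fit_linear(df, pred, invert=config.invert_linear))
        except ValueError as exc:
            failures.append(f"linear {pred}: {exc}")
        for outcome in association.OUTCOMES:
            if f"new_{outcome}" not in df.columns:
                continue
            try:
                results.append(
                    association.fit_logistic(
                        df, pred, outcome, at_risk_only=config.at_risk_only
                    )
                )
            except (ValueError, association.SeparationError) as exc:
                failures.append(f"logistic {pred}/{outcome}: {exc}")
    return results, failures


def classify_stage(
    wmh_path, ventricle_path, out_labels_path, out_csv_path,
    radii_mm=wmh_typing.DEFAULT_RADII_MM, connectivity: int = 26,
) -> pd.DataFrame:
    """File-level typing stage: NIfTI pair in, typed NIfTI + CSV out."""
    wmh = load_mask(wmh_path)
    vent = load_mask(ventricle_path)
    labels, comps, typed = wmh_typing.type_wmh(
        wmh, vent, radii_mm=radii_mm, connectivity=connectivity
    )
    save_labels(
        labels.geometry, wmh_typing.typed_label_volume(labels, comps), out_labels_path
    )
    df = pd.DataFrame(
        [
            {
                "component_id": c.component_id,
                "type": c.lesion_type,
                "n_voxels": c.n_voxels,
                "volume_ml": c.volume_ml,
            }
            for c in comps
        ]
    )
    _write_csv(df, out_csv_path)
    return df


def extract_stage(
    wmh_path, ventricle_path, out_csv_path,
    radii_mm=wmh_typing.DEFAULT_RADII_MM, connectivity: int = 26,
    surface_method: str = "marching_cubes",
) -> pd.DataFrame:
    """File-level marker stage: NIfTI pair in, per-participant marker CSV out."""
    wmh = load_mask(wmh_path)
    vent = load_mask(ventricle_path)
    labels, comps, typed = wmh_typing.type_wmh(
        wmh, vent, radii_mm=radii_mm, connectivity=connectivity
    )
    ms = shape_markers.participant_markers(typed, labels, surface_method=surface_method)
    row = {**ms.as_dict(), "wmh_volume_ml": mask_volume_ml(wmh)}
    df = pd.DataFrame([row])
    _write_csv(df, out_csv_path)
    return df


def _write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["stages"] = list(d["stages"])
    d["radii_mm"] = list(d["radii_mm"])
    return d


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
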