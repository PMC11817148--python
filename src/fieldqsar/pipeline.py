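"""End-to-end orchestration: ligands + activities in, model + reports out.

Stages: read → optional top-pose selection → train/test split (diversity
algorithm or an override file) → grid and field descriptors → column
filtering → cross-validated component selection → fit → predictions →
external-validation battery → applicability domain → contour maps.
Every stage writes a reloadable artifact into the run directory and the
manifest records all parameters, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity
from .applicability import williams_table
from .contours import coefficient_field, extract_regions, write_dx
from .field_engine import ProbeSpec, build_descriptor_matrix, build_grid, filter_columns
from .ligand_io import attach_activities, read_ligand_set, select_top_pose
from .pls import DEFAULT_CV_SEED, predict, select_n_components
from .validation import external_metrics, residual_table


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults follow the reference protocol
    (1.5 Å grid spacing, +1 test charge, 1.73 Å carbon probe, 5-fold CV,
    80% training fraction)."""

    ligands: str = ""
    activities: str = ""
    scores: str | None = None
    split_override: str | None = None
    out_dir: str = "run"
    grid_spacing: float = 1.5
    grid_margin: float = 4.0
    probe_charge: float = 1.0
    probe_radius: float = 1.73
    probe_epsilon: float = 0.0903
    elec_cap: float = 30.0
    steric_cap: float = 30.0
    min_sd: float = 0.05
    folds: int = 5
    cv_seed: int = DEFAULT_CV_SEED
    max_components: int | None = None
    scale: str = "none"
    train_fraction: float = 0.8
    upper_pct: float = 90.0
    lower_pct: float = 10.0
    ad_p_prime: int | None = None  # None -> number of PLS components

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing artifacts + manifest under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {p.name: _checksum(p) for p in paths}

    def fail(stage: str, exc: Exception) -> StageError:
        return StageError(f"stage {stage!r} failed: {exc}")

    # --- read ---------------------------------------------------------
    try:
        mols = read_ligand_set(config.ligands)
    except Exception as exc:
        raise fail("read", exc) from exc

    # --- top-pose selection (optional) ---------------------------------
    if config.scores is not None:
        try:
            scores = pd.read_csv(config.scores)
            picked = []
            for lid, group in scores.groupby("ligand_id", sort=True):
                pose_by_idx = {m.pose_index: m for m in mols if m.ligand_id == str(lid)}
                poses = [pose_by_idx[i] for i in group["pose_index"]]
                picked.append(select_top_pose(poses, group["score"].tolist()))
            mols = picked
        except Exception as exc:
            raise fail("top_pose", exc) from exc

    # --- activities -----------------------------------------------------
    try:
        ligs = attach_activities(mols, config.activities)
    except Exception as exc:
        raise fail("attach_activities", exc) from exc

    # --- split ----------------------------------------------------------
    try:
        if config.split_override:
            split = pd.read_csv(config.split_override)
            split["ligand_id"] = split["ligand_id"].astype(str)
        else:
            feats = [diversity.feature_vector(m) for m in ligs.molecules]
            train_ids, test_ids = diversity.maximin_split(
                feats, train_fraction=config.train_fraction
            )
            split = diversity.split_table(train_ids, test_ids)
        labels = dict(zip(split["ligand_id"], split["set_label"]))
        train_ids = [m.ligand_id for m in ligs.molecules if labels.get(m.ligand_id) == "train"]
        test_ids = [m.ligand_id for m in ligs.molecules if labels.get(m.ligand_id) == "test"]
        if not train_ids or not test_ids:
            raise ValueError("split produced an empty train or test set")
        split_path = out / "split.csv"
        split.to_csv(split_path, index=False)
        record("split", split_path)
    except StageError:
        raise
    except Exception as exc:
        raise fail("split", exc) from exc

    # --- fields ----------------------------------------------------------
    try:
        probe = ProbeSpec(config.probe_charge, config.probe_radius, config.probe_epsilon)
        grid = build_grid(ligs.molecules, config.grid_spacing, config.grid_margin)
        dm_full = build_descriptor_matrix(
            ligs, grid, probe, config.elec_cap, config.steric_cap
        )
        dm = filter_columns(dm_full, config.min_sd)
        fields_path = out / "fields.tsv"
        dm.to_tsv(fields_path)
        record("fields", fields_path)
    except Exception as exc:
        raise fail("fields", exc) from exc

    # --- fit --------------------------------------------------------------
    try:
        y_by_id = {r.ligand_id: r.pic50 for r in ligs.activities}
        X_train = dm.rows_for(train_ids)
        y_train = np.array([y_by_id[l] for l in train_ids])
        X_test = dm.rows_for(test_ids)
        y_test = np.array([y_by_id[l] for l in test_ids])
        model = select_n_components(
            X_train, y_train,
            folds=config.folds, seed=config.cv_seed,
            max_A=config.max_components, scale=config.scale,
            field_kind=dm.field_kind,
        )
        model_path = out / "model.json"
        model.to_json(model_path)
        record("fit", model_path)
    except Exception as exc:
        raise fail("fit", exc) from exc

    # --- predictions + residuals ------------------------------------------
    try:
        pred = pd.DataFrame({
            "ligand_id": train_ids + test_ids,
            "set_label": ["train"] * len(train_ids) + ["test"] * len(test_ids),
            "pic50_exp": np.concatenate([y_train, y_test]),
            "pic50_pred": np.concatenate(
                [predict(model, X_train), predict(model, X_test)]
            ),
        })
        residuals = residual_table(pred)
        resid_path = out / "residuals.csv"
        residuals.to_csv(resid_path, index=False, float_format="%.10g")
        record("predict", resid_path)
    except Exception as exc:
        raise fail("predict", exc) from exc

    # --- external validation -----------------------------------------------
    try:
        report = external_metrics(y_test, predict(model, X_test), q2=model.q2)
        report_path = out / "validation.json"
        report.to_json(report_path)
        record("validate", report_path)
    except Exception as exc:
        raise fail("validate", exc) from exc

    # --- applicability domain ------------------------------------------------
    try:
        ad = williams_table(
            model, X_train, y_train, X_test, y_test,
            train_ids=train_ids, test_ids=test_ids, p_prime=config.ad_p_prime,
        )
        ad_path = out / "ad_report.csv"
        ad.to_csv(ad_path)
        record("ad", ad_path, ad_path.with_suffix(".csv.meta.json"))
    except Exception as exc:
        raise fail("ad", exc) from exc

    # --- contour maps -----------------------------------------------------------
    try:
        contour_paths = []
        for kind in ("electrostatic", "steric"):
            cf = extract_regions(
                coefficient_field(model, dm, kind), config.upper_pct, config.lower_pct
            )
            dx_path = out / f"contour_{kind}.dx"
            write_dx(cf, dx_path)
            csv_path = out / f"regions_{kind}.csv"
            cf.region_summary().to_csv(csv_path, index=False, float_format="%.6g")
            contour_paths += [dx_path, csv_path]
        record("contour", *contour_paths)
    except Exception as exc:
        raise fail("contour", exc) from exc

    manifest["summary"] = {
        "n_ligands": len(ligs),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "grid_counts": list(grid.counts),
        "n_columns_retained": dm.n_columns,
        "n_components": model.n_components,
        "q2": model.q2,
        "r2_train": model.r2_train,
        "validation": report.to_dict(),
        "ad_all_in_domain": bool(ad.all_in_domain),
        "h_star": ad.h_star,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return out
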