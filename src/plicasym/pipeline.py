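"""NIfTI / CSV I/O and end-to-end orchestration.

The on-disk cohort layout consumed by :func:`run_pipeline`::

    <root>/subjects.csv              subject table
    <root>/labels.nii                integer CST label volume
    <root>/maps/<sid>_<param>.nii    per-subject scalar parameter maps
    <root>/lesions/<sid>.nii         binary lesion masks (stroke only)

All volumes must share grid shape and affine exactly (registration is
upstream of this package; nothing is resampled).  Every stage failure
aborts with a stage-tagged error, and a rerun on identical inputs
produces byte-identical tables and manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import asymmetry_table
from .cohort import (
    REGIONS,
    CohortConfig,
    LabelVolume,
    LesionMask,
    ROISample,
    generate_cohort,
    generate_label_volume,
    generate_lesion_mask,
)
from .groupstats import region_deviation_analysis
from .lesion import lesion_outcome_correlations, lesion_stats
from .validation import run_validation_grid

log = logging.getLogger("plicasym")

SUBJECT_COLUMNS = [
    "subject_id", "group", "lesioned_hemisphere",
    "fm_ue_baseline", "fm_ue_tp2", "days_to_baseline_scan", "days_to_followup",
]


class PipelineError(RuntimeError):
    """Stage-tagged failure of the end-to-end run."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    root: str  # cohort directory (layout above)
    out_dir: str
    region: str = "PLIC"
    bins: int = 10
    symmetrized: bool = False
    outcomes: tuple[str, ...] = ("fm_ue_tp2", "change_in_fm_ue")
    control_mode: str = "mean"
    seed: int = 0  # only used by simulate mode

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "outcomes" in data:
            data["outcomes"] = tuple(data["outcomes"])
        return cls(**data)


def _affine(voxel_dims) -> np.ndarray:
    return np.diag(list(voxel_dims) + [1.0])


def write_volume(path, array: np.ndarray, voxel_dims, dtype=None) -> None:
    arr = np.asarray(array)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_dims)), str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def extract_roi_sample(
    map_array: np.ndarray,
    labels: LabelVolume,
    region: str,
    hemisphere: str,
    subject_id: str = "",
    parameter: str = "",
    side: str = "",
) -> ROISample:
    """Voxel values of a map within one labelled region.

    Values come out in lexicographic (C-order) voxel-index order, which
    makes extraction deterministic and round-trips the synthetic map
    writer exactly.  NaN voxels are excluded with a logged count.
    """
    if map_array.shape != labels.grid.shape:
        raise ValueError("parameter map and labels are on different grids")
    values = np.asarray(map_array, dtype=float)[labels.region_mask(region, hemisphere)]
    if values.size == 0:
        raise ValueError(f"region {region}/{hemisphere} has no voxels")
    n_nan = int(np.isnan(values).sum())
    if n_nan:
        log.info("excluded %d NaN voxels in %s/%s (%s)", n_nan, region, hemisphere, subject_id)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValueError(f"region {region}/{hemisphere} is all-NaN")
    return ROISample(subject_id or "unknown", region, side or hemisphere, parameter, values)


# ---------------------------------------------------------------------------
# simulate mode: write a full synthetic cohort to disk
# ---------------------------------------------------------------------------

def _samples_to_maps(
    samples: list[ROISample],
    subjects,
    labels: LabelVolume,
    background: float = 0.0,
) -> dict[tuple[str, str], np.ndarray]:
    """Paint per-ROI voxel samples into 3-D maps (one per subject x parameter)."""
    hemi = {s.subject_id: s.lesioned_hemisphere for s in subjects}
    maps: dict[tuple[str, str], np.ndarray] = {}
    for s in samples:
        key = (s.subject_id, s.parameter)
        if key not in maps:
            maps[key] = np.full(labels.grid.shape, background, dtype=float)
        lesioned = hemi[s.subject_id]
        ipsi = lesioned if lesioned != "none" else "left"  # control convention
        hemisphere = ipsi if s.side == "ipsilesional" else ("right" if ipsi == "left" else "left")
        mask = labels.region_mask(s.region, hemisphere)
        if int(mask.sum()) != s.values.size:
            raise ValueError(
                f"sample size {s.values.size} != region voxel count {int(mask.sum())}"
            )
        maps[key][mask] = s.values
    return maps


def simulate_to_dir(config: CohortConfig, outdir) -> Path:
    """Generate a cohort and write the full on-disk layout.

    The number of voxels per ROI is forced to the label-box voxel count
    so that every generated sample paints exactly one region and
    extraction round-trips the generator bit-for-bit.
    """
    outdir = Path(outdir)
    (outdir / "maps").mkdir(parents=True, exist_ok=True)
    (outdir / "lesions").mkdir(parents=True, exist_ok=True)
    n_box = int(np.prod(config.box_shape))
    config = replace(config, voxels_per_roi=n_box)
    subjects, samples = generate_cohort(config)
    labels = generate_label_volume(config)

    df = pd.DataFrame([asdict(s) for s in subjects])[SUBJECT_COLUMNS]
    df.to_csv(outdir / "subjects.csv", index=False)
    write_volume(outdir / "labels.nii", labels.grid, config.voxel_dims, dtype=np.int16)
    for (sid, param), arr in _samples_to_maps(samples, subjects, labels).items():
        write_volume(outdir / "maps" / f"{sid}_{param}.nii", arr, config.voxel_dims)
    for s in subjects:
        if s.group != "stroke":
            continue
        frac = min(1.0, s.delta / config.delta_max) if config.delta_max else 0.5
        mask = generate_lesion_mask(labels, "PLIC", s.lesioned_hemisphere, frac, margin=1)
        write_volume(outdir / "lesions" / f"{s.subject_id}.nii", mask.grid, config.voxel_dims, dtype=np.uint8)
    with open(outdir / "config.yaml", "w") as fh:
        cfg = asdict(config)
        cfg["parameters"] = [asdict(p) if not isinstance(p, dict) else p for p in config.parameters]
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def _load_cohort_dir(root: Path, stage: str):
    subjects_path = root / "subjects.csv"
    if not subjects_path.exists():
        raise PipelineError(stage, f"missing subject table {subjects_path}")
    subjects = pd.read_csv(subjects_path)
    missing_cols = set(SUBJECT_COLUMNS) - set(subjects.columns)
    if missing_cols:
        raise PipelineError(stage, f"subject table lacks columns {sorted(missing_cols)}")
    grid, affine = read_volume(root / "labels.nii")
    voxel_dims = tuple(float(d) for d in np.abs(np.diag(affine)[:3]))
    code_table = {}
    for r, region in enumerate(REGIONS):
        code_table[(region, "left")] = 2 * r + 1
        code_table[(region, "right")] = 2 * r + 2
    labels = LabelVolume(grid=np.asarray(grid, dtype=int), code_table=code_table,
                         voxel_dims=voxel_dims)
    return subjects, labels, affine


def _collect_samples(root: Path, subjects: pd.DataFrame, labels: LabelVolume,
                     affine: np.ndarray) -> list[ROISample]:
    params = sorted({p.stem.split("_", 1)[1] for p in (root / "maps").glob("*.nii*")})
    if not params:
        raise PipelineError("extract", f"no parameter maps under {root / 'maps'}")
    samples: list[ROISample] = []
    for row in subjects.itertuples():
        ipsi = row.lesioned_hemisphere if row.lesioned_hemisphere != "none" else "left"
        contra = "right" if ipsi == "left" else "left"
        for param in params:
            path = root / "maps" / f"{row.subject_id}_{param}.nii"
            if not path.exists():
                raise PipelineError(
                    "extract", f"missing map for subject {row.subject_id}: {path}"
                )
            arr, aff = read_volume(path)
            if not np.allclose(aff, affine):
                raise PipelineError(
                    "extract", f"affine mismatch for {path} (no resampling is done)"
                )
            for region in REGIONS:
                for side, hemi in (("ipsilesional", ipsi), ("contralesional", contra)):
                    samples.append(
                        extract_roi_sample(arr, labels, region, hemi,
                                           subject_id=row.subject_id,
                                           parameter=param, side=side)
                    )
    return samples


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Extraction -> asymmetry -> validation -> group stats -> lesion metrics.

    Writes asymmetry.csv, validation.csv, group_stats.csv,
    lesion_stats.csv, lesion_correlations.csv and manifest.json under
    ``config.out_dir`` and returns the tables keyed by name.
    """
    root = Path(config.root)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    subjects, labels, affine = _load_cohort_dir(root, "load")
    log.info("loaded %d subjects, labels %s", len(subjects), labels.grid.shape)

    samples = _collect_samples(root, subjects, labels, affine)
    log.info("extracted %d ROI samples", len(samples))

    try:
        asym = asymmetry_table(samples, region=config.region, n_bins=config.bins,
                               symmetrized=config.symmetrized)
    except ValueError as e:
        raise PipelineError("asymmetry", str(e)) from e

    try:
        validation = run_validation_grid(asym, subjects, outcomes=config.outcomes)
    except ValueError as e:
        raise PipelineError("validation", str(e)) from e

    try:
        gstats = region_deviation_analysis(samples, subjects,
                                           control_mode=config.control_mode)
    except ValueError as e:
        raise PipelineError("groupstats", str(e)) from e

    lesion_rows, stats_list = [], []
    lesions_dir = root / "lesions"
    if lesions_dir.exists():
        for row in subjects[subjects["group"] == "stroke"].itertuples():
            path = lesions_dir / f"{row.subject_id}.nii"
            if not path.exists():
                log.info("no lesion mask for %s; skipped", row.subject_id)
                continue
            arr, aff = read_volume(path)
            if not np.allclose(aff, affine):
                raise PipelineError("lesion", f"affine mismatch for {path}")
            mask = LesionMask(grid=np.asarray(arr) > 0, voxel_dims=labels.voxel_dims)
            st = lesion_stats(row.subject_id, mask, labels, row.lesioned_hemisphere)
            stats_list.append(st)
            lesion_rows.append({
                "subject_id": st.subject_id,
                "lesion_volume_ml": st.lesion_volume_ml,
                "total_cst_load": st.total_cst_load,
                **{f"load_{k}": v for k, v in st.load_by_region.items()},
            })
    lesion_df = pd.DataFrame(lesion_rows)
    lesion_corr = (
        lesion_outcome_correlations(stats_list, subjects)
        if len(stats_list) >= 3 else pd.DataFrame()
    )

    tables = {
        "asymmetry": asym,
        "validation": validation,
        "group_stats": gstats,
        "lesion_stats": lesion_df,
        "lesion_correlations": lesion_corr,
    }
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "package": "plicasym",
        "version": __version__,
        "config": {**asdict(config), "outcomes": list(config.outcomes)},
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_subjects": int(len(subjects)),
        "n_samples": int(len(samples)),
        "tables": {name: int(len(df)) for name, df in tables.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return tables
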