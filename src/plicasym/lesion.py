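"""Lesion volume, corticospinal-tract lesion load, and correlations.

Lesion load is the percent of an anatomical label's voxels overlapped
by the binary lesion mask; the whole-CST load uses the union of the
three ipsilesional CST labels (cerebral peduncle, PLIC, corona
radiata).  Volumes are voxel counts times voxel volume, reported in
milliliters (cm³).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import REGIONS, LabelVolume, LesionMask


@dataclass
class LesionStats:
    subject_id: str
    lesion_volume_ml: float
    load_by_region: dict[str, float] = field(default_factory=dict)  # percent
    total_cst_load: float = float("nan")  # percent over union of CST labels


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    r_squared: float
    p_two_tailed: float
    n: int


def lesion_volume(mask: LesionMask) -> float:
    """Lesion volume in milliliters (voxel count x voxel volume / 1000)."""
    vx, vy, vz = mask.voxel_dims
    if vx <= 0 or vy <= 0 or vz <= 0:
        raise ValueError("voxel_dims must be > 0")
    return float(mask.grid.sum() * vx * vy * vz / 1000.0)


def lesion_load(mask: LesionMask, labels: LabelVolume, region: str, hemisphere: str) -> float:
    """Percent of the labelled region's voxels covered by the lesion."""
    if mask.grid.shape != labels.grid.shape:
        raise ValueError("lesion mask and label volume are on different grids")
    region_mask = labels.region_mask(region, hemisphere)
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise ValueError(f"region {region}/{hemisphere} has no voxels")
    return 100.0 * int((mask.grid & region_mask).sum()) / n_region


def total_cst_load(mask: LesionMask, labels: LabelVolume, hemisphere: str) -> float:
    """Percent overlap with the union of the three CST labels."""
    if mask.grid.shape != labels.grid.shape:
        raise ValueError("lesion mask and label volume are on different grids")
    union = np.zeros(labels.grid.shape, dtype=bool)
    for region in REGIONS:
        union |= labels.region_mask(region, hemisphere)
    n = int(union.sum())
    if n == 0:
        raise ValueError(f"no CST voxels in hemisphere {hemisphere}")
    return 100.0 * int((mask.grid & union).sum()) / n


def lesion_stats(
    subject_id: str, mask: LesionMask, labels: LabelVolume, hemisphere: str
) -> LesionStats:
    return LesionStats(
        subject_id=subject_id,
        lesion_volume_ml=lesion_volume(mask),
        load_by_region={
            region: lesion_load(mask, labels, region, hemisphere) for region in REGIONS
        },
        total_cst_load=total_cst_load(mask, labels, hemisphere),
    )


def correlate(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Pearson correlation with the two-tailed t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input; correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(x_name, y_name, r, r * r, float(res.pvalue), int(x.size))


def lesion_outcome_correlations(
    stats_list: list[LesionStats], subjects: pd.DataFrame
) -> pd.DataFrame:
    """Correlate volume and per-region loads with FM-UE outcomes.

    Returns a tidy table (x_name, y_name, r, r_squared, p_two_tailed, n)
    over lesion volume, each region's load, and the whole-CST load,
    against baseline FM-UE, FM-UE at follow-up, and the change score.
    """
    subj = subjects.copy()
    if "change_in_fm_ue" not in subj.columns:
        subj["change_in_fm_ue"] = subj["fm_ue_tp2"] - subj["fm_ue_baseline"]
    subj = subj.set_index("subject_id")
    frame = pd.DataFrame(
        {
            "lesion_volume_ml": {s.subject_id: s.lesion_volume_ml for s in stats_list},
            "total_cst_load": {s.subject_id: s.total_cst_load for s in stats_list},
            **{
                f"load_{region}": {
                    s.subject_id: s.load_by_region.get(region, np.nan)
                    for s in stats_list
                }
                for region in REGIONS
            },
        }
    )
    rows = []
    for x_name in frame.columns:
        for y_name in ("fm_ue_baseline", "fm_ue_tp2", "change_in_fm_ue"):
            x = frame[x_name]
            y = subj.loc[frame.index, y_name]
            try:
                res = correlate(x.to_numpy(), y.to_numpy(), x_name, y_name)
                rows.append(vars(res))
            except ValueError:
                rows.append(
                    dict(x_name=x_name, y_name=y_name, r=np.nan, r_squared=np.nan,
                         p_two_tailed=np.nan, n=len(x))
                )
    return pd.DataFrame(rows)
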