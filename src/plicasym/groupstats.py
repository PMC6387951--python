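"""Deviation-from-control group comparisons with Holm correction.

Three families of tests over region x parameter cells:

* paired two-tailed t-tests, left vs right hemisphere in controls;
* paired two-tailed t-tests, ipsilesional vs contralesional in stroke;
* two-sample heteroscedastic (Welch) t-tests, stroke ipsilesional vs
  controls.

P-values are Holm step-down adjusted within a family; by default a
family is all parameters sharing one region and test kind, and both raw
and adjusted p are reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import REGIONS


@dataclass
class GroupTestResult:
    region: str
    parameter: str
    test_kind: str  # "paired" | "welch"
    t_stat: float
    df: float  # integer for paired, fractional Welch-Satterthwaite
    p_raw: float
    p_holm: float = float("nan")
    family_id: str = ""
    n: int = 0


def t_two_tailed_p(t_stat: float, df: float) -> float:
    """Two-tailed Student-t tail probability at |t_stat|."""
    if df <= 0:
        raise ValueError("degrees of freedom must be > 0")
    return float(2.0 * stats.t.sf(abs(t_stat), df))


def paired_t(a, b, region: str = "", parameter: str = "") -> GroupTestResult:
    """Paired two-tailed t-test on matched vectors a, b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired test needs equal-length vectors, n >= 2")
    d = a - b
    if np.ptp(d) == 0.0 and d[0] != 0.0:
        raise ValueError("zero-variance nonzero differences; t undefined")
    res = stats.ttest_rel(a, b)
    t = float(res.statistic) if np.isfinite(res.statistic) else 0.0
    df = a.size - 1
    p = t_two_tailed_p(t, df)
    return GroupTestResult(region, parameter, "paired", t, float(df), p, n=a.size)


def welch_t(a, b, region: str = "", parameter: str = "") -> GroupTestResult:
    """Two-sample heteroscedastic (Welch) two-tailed t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test needs n >= 2 in both groups")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
        raise ValueError("zero variance in both groups; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupTestResult(
        region, parameter, "welch",
        float(res.statistic), float(res.df), float(res.pvalue),
        n=a.size + b.size,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def _subject_region_means(samples) -> pd.DataFrame:
    rows = [
        {
            "subject_id": s.subject_id,
            "region": s.region,
            "side": s.side,
            "parameter": s.parameter,
            "mean": float(np.mean(s.values)),
        }
        for s in samples
    ]
    return pd.DataFrame(rows)


def region_deviation_analysis(
    samples,
    subjects: pd.DataFrame,
    regions=REGIONS,
    control_mode: str = "mean",
) -> pd.DataFrame:
    """All three test families over every region x parameter cell.

    ``samples`` are ROISample-like objects for the whole cohort (controls
    carry their left hemisphere in the "ipsilesional" slot by
    convention).  ``control_mode`` picks the control reference for the
    Welch comparison: "mean" (average of both hemispheres per control,
    one number each — the default, avoiding double counting), "left"
    or "right" (single-hemisphere).

    Returns a tidy table (region, parameter, test_kind, t, df, p_raw,
    p_holm, family_id, n); Holm is applied within each region x
    test-kind family across parameters.  Cells whose test cannot be
    computed are reported with NaN statistics.
    """
    if control_mode not in ("mean", "left", "right"):
        raise ValueError("control_mode must be 'mean', 'left' or 'right'")
    means = _subject_region_means(samples)
    groups = subjects.set_index("subject_id")["group"]
    means["group"] = means["subject_id"].map(groups)
    if means["group"].isna().any():
        missing = means.loc[means["group"].isna(), "subject_id"].unique()
        raise ValueError(f"samples for unknown subjects: {list(missing)}")
    parameters = sorted(means["parameter"].unique())

    results: list[GroupTestResult] = []
    for region in regions:
        reg = means[means["region"] == region]
        pivot = reg.pivot_table(
            index=["group", "subject_id"], columns=["parameter", "side"],
            values="mean", sort=True,
        )
        for kind in ("paired_control", "paired_stroke", "welch"):
            fam: list[GroupTestResult] = []
            for param in parameters:
                try:
                    if kind == "paired_control":
                        sub = pivot.loc["control", param]
                        r = paired_t(
                            sub["ipsilesional"], sub["contralesional"],
                            region, param,
                        )
                        r.test_kind = "paired_control"
                    elif kind == "paired_stroke":
                        sub = pivot.loc["stroke", param]
                        r = paired_t(
                            sub["ipsilesional"], sub["contralesional"],
                            region, param,
                        )
                        r.test_kind = "paired_stroke"
                    else:
                        stroke_ipsi = pivot.loc["stroke", (param, "ipsilesional")]
                        ctrl = pivot.loc["control", param]
                        if control_mode == "mean":
                            ctrl_ref = ctrl.mean(axis=1)
                        elif control_mode == "left":
                            ctrl_ref = ctrl["ipsilesional"]  # left by convention
                        else:
                            ctrl_ref = ctrl["contralesional"]
                        r = welch_t(stroke_ipsi, ctrl_ref, region, param)
                except (KeyError, ValueError):
                    r = GroupTestResult(
                        region, param, kind,
                        float("nan"), float("nan"), float("nan"),
                    )
                r.family_id = f"{region}:{kind}"
                fam.append(r)
            valid = [r for r in fam if np.isfinite(r.p_raw)]
            if valid:
                adj = holm_adjust([r.p_raw for r in valid])
                for r, p in zip(valid, adj):
                    r.p_holm = float(p)
            results.extend(fam)
    return pd.DataFrame([vars(r) for r in results]).rename(
        columns={"t_stat": "t"}
    )
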