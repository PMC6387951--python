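"""Exhaustive combination validation of asymmetry-outcome regressions.

For a cohort of n subjects, every possible split into n-3 training and
3 held-out subjects is enumerated (84 splits for n = 9).  An ordinary
least-squares line is fit on each training set and scored by normalized
RMSE on its test triple; the "line of best fit" is the training line
whose test NRMSE is closest to the mean test NRMSE, and the final NRMSE
is that line's error over all subjects.  The optimism-adjusted r²
shrinks the full-data r² by the mean excess of the training-set r²
values over it:

    r2_adjusted = r2_full - mean_i(r2_train_i - r2_full)

The whole procedure is deterministic: splits are enumerated in
lexicographic order of test-index tuples and ties in the best-line
selection break to the earliest split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd


@dataclass
class SplitResult:
    train_ids: tuple
    test_ids: tuple
    slope: float
    intercept: float
    r2_train: float
    nrmse_test: float


@dataclass
class ValidationSummary:
    predictor: str
    outcome: str
    n: int
    splits: list[SplitResult]
    r2_full: float
    r2_adjusted: float
    mean_nrmse_test: float
    best_line: SplitResult
    final_nrmse: float
    slope_full: float = float("nan")
    intercept_full: float = float("nan")
    dropped_ids: tuple = field(default_factory=tuple)


def enumerate_splits(n: int, k_test: int = 3) -> list[tuple[tuple, tuple]]:
    """All C(n, k_test) (train, test) index splits, lexicographic in test."""
    if k_test < 1 or n <= k_test:
        raise ValueError("need n > k_test >= 1")
    out = []
    full = set(range(n))
    for test in combinations(range(n), k_test):
        train = tuple(sorted(full - set(test)))
        out.append((train, test))
    assert len(out) == comb(n, k_test)
    return out


def fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS line (slope, intercept, r2); constant y gives r2 = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (x, y) points")
    if np.ptp(x) == 0.0:
        raise ValueError("predictor is constant; line undefined")
    slope, intercept = np.polyfit(x, y, 1)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant outcome; r2 defined as 0", stacklevel=2)
        return float(slope), float(intercept), 0.0
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    return float(slope), float(intercept), 1.0 - ss_res / ss_tot


def nrmse(predicted: np.ndarray, observed: np.ndarray, normalizer: float) -> float:
    """RMS error divided by a scale (here: full-cohort outcome range)."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.size != observed.size or predicted.size < 1:
        raise ValueError("predicted and observed must have equal length >= 1")
    if normalizer <= 0:
        raise ValueError("normalizer must be > 0")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)) / normalizer)


def select_best_line(splits: list[SplitResult]) -> SplitResult:
    """Split whose test NRMSE is nearest the mean; ties to earliest."""
    if not splits:
        raise ValueError("no splits to select from")
    mean_nrmse = float(np.mean([s.nrmse_test for s in splits]))
    return min(splits, key=lambda s: abs(s.nrmse_test - mean_nrmse))


def optimism_adjusted_r2(r2_full: float, r2_train_list) -> float:
    """Full-data r2 minus the mean training-set optimism."""
    r2_train_list = np.asarray(r2_train_list, dtype=float)
    if r2_train_list.size == 0:
        raise ValueError("need at least one training r2")
    return float(r2_full - np.mean(r2_train_list - r2_full))


def validate(
    predictor_values,
    outcomes,
    subject_ids=None,
    k_test: int = 3,
    predictor: str = "predictor",
    outcome: str = "outcome",
) -> ValidationSummary:
    """Run the full combination-validation procedure.

    Subjects with a missing predictor or outcome are dropped with a
    warning; fewer than five complete subjects is an error.  The NRMSE
    normalizer is the range of the observed outcome over the retained
    cohort, applied identically to per-split and final NRMSE.
    """
    x = np.asarray(predictor_values, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.size != y.size:
        raise ValueError("predictor and outcome must have equal length")
    ids = np.asarray(
        subject_ids if subject_ids is not None else np.arange(x.size), dtype=object
    )
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = tuple(ids[~keep])
    if dropped:
        warnings.warn(f"dropping subjects with missing values: {dropped}", stacklevel=2)
        x, y, ids = x[keep], y[keep], ids[keep]
    n = x.size
    if n < 5:
        raise ValueError("need at least five subjects with complete data")
    normalizer = float(np.ptp(y))
    if normalizer == 0.0:
        raise ValueError("outcome has zero range; NRMSE undefined")

    splits = []
    for train, test in enumerate_splits(n, k_test):
        tr, te = np.array(train), np.array(test)
        slope, intercept, r2_train = fit_line(x[tr], y[tr])
        err = nrmse(slope * x[te] + intercept, y[te], normalizer)
        splits.append(
            SplitResult(tuple(ids[tr]), tuple(ids[te]), slope, intercept, r2_train, err)
        )
    slope_full, intercept_full, r2_full = fit_line(x, y)
    best = select_best_line(splits)
    final = nrmse(best.slope * x + best.intercept, y, normalizer)
    return ValidationSummary(
        predictor=predictor,
        outcome=outcome,
        n=n,
        splits=splits,
        r2_full=r2_full,
        r2_adjusted=optimism_adjusted_r2(r2_full, [s.r2_train for s in splits]),
        mean_nrmse_test=float(np.mean([s.nrmse_test for s in splits])),
        best_line=best,
        final_nrmse=final,
        slope_full=slope_full,
        intercept_full=intercept_full,
        dropped_ids=dropped,
    )


def run_validation_grid(
    asymmetry: pd.DataFrame,
    subjects: pd.DataFrame,
    outcomes: tuple[str, ...] = ("fm_ue_tp2", "change_in_fm_ue"),
    predictors: tuple[str, ...] = ("delta_mean", "log_delta_kld"),
    k_test: int = 3,
) -> pd.DataFrame:
    """Validation over every parameter x predictor x outcome cell.

    ``asymmetry`` is an asymmetry_table output; ``subjects`` must carry
    subject_id, group, fm_ue_baseline, fm_ue_tp2.  Only stroke subjects
    enter the regression.  Returns one row per cell with the summary
    statistics (r2_full, r2_adjusted, mean/final NRMSE, best line).
    """
    subj = subjects.copy()
    if "change_in_fm_ue" not in subj.columns:
        subj["change_in_fm_ue"] = subj["fm_ue_tp2"] - subj["fm_ue_baseline"]
    stroke = subj[subj["group"] == "stroke"].set_index("subject_id")
    rows = []
    for param, grp in asymmetry.groupby("parameter"):
        grp = grp[grp["subject_id"].isin(stroke.index)].set_index("subject_id")
        for pred in predictors:
            for out in outcomes:
                x = grp[pred].reindex(stroke.index)
                y = stroke[out]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    summary = validate(
                        x.to_numpy(), y.to_numpy(), subject_ids=stroke.index.to_numpy(),
                        k_test=k_test, predictor=f"{param} {pred}", outcome=out,
                    )
                rows.append({
                    "parameter": param,
                    "predictor_type": pred,
                    "outcome": out,
                    "n": summary.n,
                    "r2_full": summary.r2_full,
                    "r2_adjusted": summary.r2_adjusted,
                    "mean_nrmse_test": summary.mean_nrmse_test,
                    "final_nrmse": summary.final_nrmse,
                    "best_line_slope": summary.best_line.slope,
                    "best_line_intercept": summary.best_line.intercept,
                })
    return pd.DataFrame(rows)
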