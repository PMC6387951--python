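"""Interhemispheric microstructural asymmetry statistics.

Two statistics compare the distribution of a microstructural parameter
(ODI, FA, GFA, ...) between the contralesional (C) and ipsilesional (I)
sides of a region of interest — canonically the posterior limb of the
internal capsule (PLIC):

* the mean difference  ``delta_mean = mean(C) - mean(I)``;
* the half Kullback-Leibler divergence

      delta_kld = 1/2 * sum_i p_C(i) * ln(p_C(i) / p_I(i))

  computed over a shared 10-bin histogram whose bin probabilities are
  estimated with James-Stein shrinkage toward the uniform distribution
  (the entropy-package ``KL.shrink`` estimator).  The log transform of
  delta_kld serves as the regression predictor downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class HistogramPair:
    """Shared-edge histograms of a contralesional/ipsilesional pair."""

    edges: np.ndarray  # n_bins + 1 ascending boundaries
    counts_c: np.ndarray
    counts_i: np.ndarray
    n_bins: int
    degenerate: bool = False  # pooled range was zero -> single bin


@dataclass
class AsymmetryResult:
    subject_id: str
    region: str
    parameter: str
    delta_mean: float
    delta_kld: float
    log_delta_kld: float  # NaN when delta_kld <= 0
    degenerate: bool = False


def delta_mean(contra_values: np.ndarray, ipsi_values: np.ndarray) -> float:
    """Interhemispheric mean difference, mean(contra) - mean(ipsi)."""
    c = np.asarray(contra_values, dtype=float)
    i = np.asarray(ipsi_values, dtype=float)
    if c.size == 0 or i.size == 0:
        raise ValueError("ROI samples must be nonempty")
    return float(c.mean() - i.mean())


def shared_histogram(
    contra_values: np.ndarray, ipsi_values: np.ndarray, n_bins: int = 10
) -> HistogramPair:
    """Histogram both samples on common equal-width bins.

    Edges span the pooled min-max; bins are half-open [e_i, e_{i+1})
    with the last bin closed (numpy's convention).  A zero pooled range
    collapses to a single degenerate bin holding everything, flagged so
    callers can report it.
    """
    c = np.asarray(contra_values, dtype=float)
    i = np.asarray(ipsi_values, dtype=float)
    if c.size == 0 or i.size == 0:
        raise ValueError("ROI samples must be nonempty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pooled = np.concatenate([c, i])
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        return HistogramPair(
            edges=np.array([lo, hi]),
            counts_c=np.array([c.size]),
            counts_i=np.array([i.size]),
            n_bins=1,
            degenerate=True,
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    counts_c, _ = np.histogram(c, bins=edges)
    counts_i, _ = np.histogram(i, bins=edges)
    return HistogramPair(edges=edges, counts_c=counts_c, counts_i=counts_i, n_bins=n_bins)


def shrink_probabilities(counts: np.ndarray) -> np.ndarray:
    """James-Stein shrinkage estimate of bin probabilities.

    Shrinks the empirical frequencies theta_k = counts_k / N toward the
    uniform target 1/B with intensity

        lambda* = (1 - sum theta_k^2) / ((N-1) * sum (1/B - theta_k)^2)

    clipped to [0, 1]; a zero denominator (empirical already uniform)
    returns the uniform distribution.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need a 1-D vector of at least two bin counts")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    n = counts.sum()
    if n < 1:
        raise ValueError("total count must be >= 1")
    b = counts.size
    theta = counts / n
    target = np.full(b, 1.0 / b)
    denom = (n - 1.0) * np.sum((target - theta) ** 2)
    if denom == 0.0:
        return target
    lam = float(np.clip((1.0 - np.sum(theta**2)) / denom, 0.0, 1.0))
    return lam * target + (1.0 - lam) * theta


def _kl_directed(p: np.ndarray, q: np.ndarray) -> float:
    # 0 * ln(0/q) := 0; p > 0 with q = 0 -> +inf
    out = 0.0
    for pk, qk in zip(p, q):
        if pk == 0.0:
            continue
        if qk == 0.0:
            return float("inf")
        out += pk * np.log(pk / qk)
    return out


def delta_kld(
    contra_values: np.ndarray,
    ipsi_values: np.ndarray,
    n_bins: int = 10,
    symmetrized: bool = False,
    eps_floor: float | None = None,
) -> float:
    """Half Kullback-Leibler divergence of the shrunk histograms (nats).

    Default is the directional form (1/2) * D(C || I).  With
    ``symmetrized=True`` it returns (1/2) * [D(C||I) + D(I||C)], i.e.
    the Jeffreys-type symmetrization with the same 1/2 prefactor.
    ``eps_floor`` optionally floors zero probabilities (renormalized)
    to keep the value finite; off by default, matching the statistic's
    unbounded (0, inf) range.
    """
    hist = shared_histogram(contra_values, ipsi_values, n_bins=n_bins)
    if hist.degenerate:
        return 0.0
    p_c = shrink_probabilities(hist.counts_c)
    p_i = shrink_probabilities(hist.counts_i)
    if eps_floor is not None:
        p_c = np.maximum(p_c, eps_floor)
        p_i = np.maximum(p_i, eps_floor)
        p_c /= p_c.sum()
        p_i /= p_i.sum()
    val = _kl_directed(p_c, p_i)
    if symmetrized:
        val = val + _kl_directed(p_i, p_c)
    return 0.5 * val


def log_kld(kld_value: float) -> float:
    """Natural log of a positive divergence; NaN for kld <= 0."""
    if kld_value > 0.0:
        return float(np.log(kld_value))
    return float("nan")


def asymmetry_result(
    subject_id: str,
    region: str,
    parameter: str,
    contra_values: np.ndarray,
    ipsi_values: np.ndarray,
    n_bins: int = 10,
    symmetrized: bool = False,
) -> AsymmetryResult:
    """Both asymmetry statistics for one subject x region x parameter."""
    hist = shared_histogram(contra_values, ipsi_values, n_bins=n_bins)
    kld = delta_kld(contra_values, ipsi_values, n_bins=n_bins, symmetrized=symmetrized)
    return AsymmetryResult(
        subject_id=subject_id,
        region=region,
        parameter=parameter,
        delta_mean=delta_mean(contra_values, ipsi_values),
        delta_kld=kld,
        log_delta_kld=log_kld(kld),
        degenerate=hist.degenerate,
    )


def asymmetry_table(
    samples,
    region: str = "PLIC",
    n_bins: int = 10,
    symmetrized: bool = False,
) -> pd.DataFrame:
    """Per-subject x parameter asymmetry table for one region.

    ``samples`` is an iterable of ROISample-like objects (subject_id,
    region, side, parameter, values).  Returns a tidy DataFrame with
    columns subject_id, region, parameter, delta_mean, delta_kld,
    log_delta_kld, degenerate.
    """
    by_key: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for s in samples:
        if s.region != region:
            continue
        by_key.setdefault((s.subject_id, s.parameter), {})[s.side] = s.values
    rows = []
    for (sid, param), sides in sorted(by_key.items()):
        if "contralesional" not in sides or "ipsilesional" not in sides:
            raise ValueError(f"incomplete side pair for {sid}/{param} in {region}")
        res = asymmetry_result(
            sid, region, param, sides["contralesional"], sides["ipsilesional"],
            n_bins=n_bins, symmetrized=symmetrized,
        )
        rows.append(vars(res))
    return pd.DataFrame(rows)
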