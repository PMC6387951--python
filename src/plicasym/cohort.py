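"""Synthetic stroke/control cohort generator.

Emulates the statistical structure a PLIC-asymmetry analysis assumes:
a cohort of stroke patients whose ipsilesional corticospinal-tract voxel
distributions are shifted relative to the contralesional side by a
per-subject severity, with follow-up Fugl-Meyer Upper-Extremity (FM-UE)
scores linearly determined by that severity plus noise; and healthy
controls with identically distributed hemispheres.  Label volumes and
lesion masks are built with exactly known geometry so that downstream
region statistics have analytic ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

REGIONS = ("cerebral_peduncle", "PLIC", "corona_radiata")
SIDES = ("ipsilesional", "contralesional")

FM_UE_MAX = 66
FM_UE_BASELINE_CAP = 50  # inclusion criterion: baseline FM-UE <= 50


@dataclass(frozen=True)
class ParameterSpec:
    """Distributional model for one microstructural parameter map.

    family:
        "truncnorm" — normal truncated to [0, 1] (ODI, FA, GFA, RDI);
        "lognormal" — positive unbounded (diffusivities, µm²/ms).
    mean, spread:
        contralesional mean and standard deviation on the natural scale.
    shift_sign:
        +1 if the ipsilesional distribution shifts upward after stroke
        (ODI), -1 if downward (FA, GFA, AD).
    effect_scale:
        multiplies the per-subject severity before it is applied as a
        shift for this parameter (1.0 keeps shift == severity).
    """

    name: str
    family: str
    mean: float
    spread: float
    shift_sign: int = 1
    effect_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("truncnorm", "lognormal"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.spread <= 0:
            raise ValueError("parameter spread must be > 0")
        if self.family == "truncnorm" and not 0.0 <= self.mean <= 1.0:
            raise ValueError("truncnorm mean must lie in [0, 1]")
        if self.family == "lognormal" and self.mean <= 0:
            raise ValueError("lognormal mean must be > 0")
        if self.shift_sign not in (-1, 1):
            raise ValueError("shift_sign must be +1 or -1")


#: Default parameter battery.  Means/spreads are plausible white-matter
#: values for each index; shift signs follow the direction of the
#: stroke-vs-contralesional differences the analysis is built to detect
#: (ODI up; FA, GFA, AD down; MD, RD up).  Diffusivities in µm²/ms.
DEFAULT_PARAMETERS: tuple[ParameterSpec, ...] = (
    ParameterSpec("ODI", "truncnorm", 0.25, 0.05, +1),
    ParameterSpec("FA", "truncnorm", 0.60, 0.08, -1),
    ParameterSpec("GFA", "truncnorm", 0.55, 0.08, -1),
    ParameterSpec("RDI", "truncnorm", 0.45, 0.07, +1),
    ParameterSpec("MD", "lognormal", 0.75, 0.10, +1),
    ParameterSpec("AD", "lognormal", 1.20, 0.15, -1),
    ParameterSpec("RD", "lognormal", 0.55, 0.10, +1),
)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate a cohort reproducibly."""

    n_stroke: int = 9
    n_control: int = 9
    parameters: tuple[ParameterSpec, ...] = DEFAULT_PARAMETERS
    voxels_per_roi: int = 500
    #: per-subject ipsilesional shift drawn uniformly from [0, delta_max]
    delta_max: float = 0.12
    #: FM-UE tp2 = clamp(round(intercept - slope * delta + noise), 0, 66)
    outcome_intercept: float = 60.0
    outcome_slope: float = 450.0
    outcome_noise_sd: float = 6.0
    baseline_intercept: float = 45.0
    baseline_noise_sd: float = 8.0
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    box_shape: tuple[int, int, int] = (6, 6, 6)
    voxel_dims: tuple[float, float, float] = (1.9, 1.9, 2.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stroke <= 0 or self.n_control <= 0:
            raise ValueError("cohort counts must be > 0")
        if self.voxels_per_roi <= 0:
            raise ValueError("voxels_per_roi must be > 0")
        if self.delta_max < 0:
            raise ValueError("delta_max must be >= 0")
        if self.outcome_noise_sd < 0 or self.baseline_noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be > 0")
        if len(self.grid_shape) != 3 or len(self.box_shape) != 3:
            raise ValueError("grid_shape and box_shape must be 3-D")
        if not self.parameters:
            raise ValueError("at least one parameter required")


def noise_sd_for_r2(config: CohortConfig, target_r2: float) -> float:
    """Outcome noise SD giving a generating predictor-outcome r².

    The noiseless outcome varies by slope * delta with delta uniform on
    [0, delta_max] (variance delta_max²/12); choosing
    sigma = slope * sd(delta) * sqrt(1/r² - 1) makes the population
    squared correlation between delta and the outcome equal target_r2.
    """
    if not 0 < target_r2 <= 1:
        raise ValueError("target_r2 must be in (0, 1]")
    signal_sd = abs(config.outcome_slope) * config.delta_max / np.sqrt(12.0)
    return signal_sd * np.sqrt(1.0 / target_r2 - 1.0)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str  # "stroke" | "control"
    lesioned_hemisphere: str  # "left" | "right" | "none"
    fm_ue_baseline: int
    fm_ue_tp2: int
    days_to_baseline_scan: int
    days_to_followup: int
    #: generating severity (ground truth, not observable clinically)
    delta: float = 0.0

    def __post_init__(self) -> None:
        if (self.group == "stroke") != (self.lesioned_hemisphere != "none"):
            raise ValueError("group=stroke iff lesioned_hemisphere != none")
        for s in (self.fm_ue_baseline, self.fm_ue_tp2):
            if not 0 <= s <= FM_UE_MAX:
                raise ValueError("FM-UE scores must lie in [0, 66]")
        if self.group == "stroke" and self.fm_ue_baseline > FM_UE_BASELINE_CAP:
            raise ValueError("stroke baseline FM-UE must be <= 50")


@dataclass
class ROISample:
    """Voxel values of one parameter in one region/side of one subject."""

    subject_id: str
    region: str
    side: str  # "ipsilesional" | "contralesional"
    parameter: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("ROISample values must be nonempty")


@dataclass
class LabelVolume:
    grid: np.ndarray  # 3-D int array, 0 = background
    code_table: dict[tuple[str, str], int]  # (region, hemisphere) -> code
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        codes = set(self.code_table.values())
        if len(codes) != len(self.code_table):
            raise ValueError("region codes must be unique")
        present = set(np.unique(self.grid)) - {0}
        if not present <= codes:
            raise ValueError("grid contains codes missing from code_table")

    def code(self, region: str, hemisphere: str) -> int:
        try:
            return self.code_table[(region, hemisphere)]
        except KeyError:
            raise KeyError(f"no label code for {region}/{hemisphere}") from None

    def region_mask(self, region: str, hemisphere: str) -> np.ndarray:
        return self.grid == self.code(region, hemisphere)


@dataclass
class LesionMask:
    grid: np.ndarray  # 3-D bool array
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)


def _truncnorm_sample(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_sample(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    # moment-matched log-normal: given arithmetic mean m and SD s
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _draw_roi(
    rng: np.random.Generator, spec: ParameterSpec, shift: float, size: int
) -> np.ndarray:
    mean = spec.mean + shift
    if spec.family == "truncnorm":
        mean = float(np.clip(mean, 0.0, 1.0))
        return _truncnorm_sample(rng, mean, spec.spread, size)
    if mean <= 0:
        raise ValueError("shift drives log-normal mean non-positive")
    return _lognormal_sample(rng, mean, spec.spread, size)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SubjectRecord], list[ROISample]]:
    """Generate subject records and per-ROI voxel samples.

    Stroke subjects draw a severity delta ~ U[0, delta_max]; their
    ipsilesional samples come from the contralesional distribution
    shifted by shift_sign * effect_scale * delta (in all three CST
    regions), and FM-UE follow-up is a clamped, rounded linear function
    of delta.  Controls have identically distributed hemispheres; their
    left hemisphere is mapped to the "ipsilesional" slot by convention so
    downstream code treats both groups uniformly.  Identical configs
    (including seed) reproduce outputs bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectRecord] = []
    samples: list[ROISample] = []

    ideal_baseline = config.baseline_intercept
    if ideal_baseline > FM_UE_BASELINE_CAP:
        warnings.warn(
            "baseline outcome model exceeds the FM-UE <= 50 inclusion "
            "criterion for small severities; scores will be clamped",
            stacklevel=2,
        )

    for j in range(config.n_stroke + config.n_control):
        is_stroke = j < config.n_stroke
        sid = f"S{j + 1}" if is_stroke else f"C{j - config.n_stroke + 1}"
        if is_stroke:
            delta = rng.uniform(0.0, config.delta_max) if config.delta_max else 0.0
            hemi = "left" if rng.random() < 0.5 else "right"
            eps_tp2 = rng.normal(0.0, config.outcome_noise_sd) if config.outcome_noise_sd else 0.0
            eps_bl = rng.normal(0.0, config.baseline_noise_sd) if config.baseline_noise_sd else 0.0
            tp2 = int(np.clip(round(
                config.outcome_intercept - config.outcome_slope * delta + eps_tp2
            ), 0, FM_UE_MAX))
            baseline = int(np.clip(round(
                config.baseline_intercept - config.outcome_slope * delta + eps_bl
            ), 0, FM_UE_BASELINE_CAP))
        else:
            delta = 0.0
            hemi = "none"
            tp2 = baseline = FM_UE_MAX
        days_bl = int(rng.integers(3, 14))  # >2 and <14 days post-onset
        days_fu = int(round(np.clip(rng.normal(38.0, 9.0), days_bl + 7, None)))
        subjects.append(
            SubjectRecord(sid, "stroke" if is_stroke else "control", hemi,
                          baseline, tp2, days_bl, days_fu, delta=delta)
        )
        for spec in config.parameters:
            shift = spec.shift_sign * spec.effect_scale * delta if is_stroke else 0.0
            for region in REGIONS:
                contra = _draw_roi(rng, spec, 0.0, config.voxels_per_roi)
                ipsi = _draw_roi(rng, spec, shift, config.voxels_per_roi)
                samples.append(ROISample(sid, region, "contralesional", spec.name, contra))
                samples.append(ROISample(sid, region, "ipsilesional", spec.name, ipsi))
    return subjects, samples


# six codes: region index * 2 + (1 left, 2 right)
def _default_code_table() -> dict[tuple[str, str], int]:
    table = {}
    for r, region in enumerate(REGIONS):
        table[(region, "left")] = 2 * r + 1
        table[(region, "right")] = 2 * r + 2
    return table


def generate_label_volume(config: CohortConfig) -> LabelVolume:
    """Toy CST label volume: six disjoint axis-aligned boxes.

    One box per region x hemisphere, stacked along z (cerebral peduncle
    inferior, PLIC middle, corona radiata superior), with left/right
    boxes mirror-symmetric about the midsagittal plane (x axis).
    """
    X, Y, Z = config.grid_shape
    bx, by, bz = config.box_shape
    if X < 2 * (bx + 1) or Y < by or Z < 3 * bz + 2:
        raise ValueError(
            f"grid {config.grid_shape} too small for six {config.box_shape} "
            "boxes (need x >= 2*(bx+1), y >= by, z >= 3*bz+2)"
        )
    grid = np.zeros((X, Y, Z), dtype=np.int16)
    table = _default_code_table()
    x_left = X // 2 - bx - 1 if X // 2 - bx - 1 >= 0 else 0
    x_right = X - x_left - bx  # mirror of [x_left, x_left+bx) under i -> X-1-i
    y0 = (Y - by) // 2
    z_gap = (Z - 3 * bz) // 4
    for r, region in enumerate(REGIONS):
        z0 = z_gap + r * (bz + z_gap)
        grid[x_left:x_left + bx, y0:y0 + by, z0:z0 + bz] = table[(region, "left")]
        grid[x_right:x_right + bx, y0:y0 + by, z0:z0 + bz] = table[(region, "right")]
    return LabelVolume(grid=grid, code_table=table, voxel_dims=config.voxel_dims)


def generate_lesion_mask(
    labels: LabelVolume,
    region: str,
    hemisphere: str,
    overlap_fraction: float,
    margin: int = 0,
) -> LesionMask:
    """Lesion mask covering an exact fraction of one labelled region.

    The mask contains floor(overlap_fraction * |region|) voxels of the
    target region (the first in lexicographic voxel order), plus — if
    margin > 0 — a dilated halo restricted to voxels OUTSIDE the target
    region, so the constructed overlap count is exact regardless of
    margin.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    region_mask = labels.region_mask(region, hemisphere)  # KeyError if unknown
    n_region = int(region_mask.sum())
    if n_region == 0:
        raise ValueError(f"region {region}/{hemisphere} has no voxels")
    k = int(np.floor(overlap_fraction * n_region))
    mask = np.zeros_like(region_mask, dtype=bool)
    if k:
        idx = np.argwhere(region_mask)[:k]  # argwhere is C-order = lexicographic
        mask[tuple(idx.T)] = True
    if margin > 0:
        from scipy import ndimage

        halo = ndimage.binary_dilation(mask, iterations=margin)
        mask |= halo & ~region_mask
    return LesionMask(grid=mask, voxel_dims=labels.voxel_dims)
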