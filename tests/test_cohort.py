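"""Synthetic cohort generator: structure, determinism, effect injection."""

import numpy as np
import pytest

from plicasym import (
    CohortConfig,
    ParameterSpec,
    generate_cohort,
    generate_label_volume,
    generate_lesion_mask,
    noise_sd_for_r2,
)

ODI = ParameterSpec("ODI", "truncnorm", 0.25, 0.05, +1)
FA = ParameterSpec("FA", "truncnorm", 0.60, 0.08, -1)
AD = ParameterSpec("AD", "lognormal", 1.20, 0.15, -1)


def _mean_diff(samples, sid, param, region="PLIC"):
    sides = {
        s.side: s.values
        for s in samples
        if s.subject_id == sid and s.parameter == param and s.region == region
    }
    return sides["ipsilesional"].mean() - sides["contralesional"].mean()


class TestGenerateCohort:
    def test_cohort_composition(self, cohort):
        subjects, samples = cohort
        assert len(subjects) == 18
        assert sum(s.lesioned_hemisphere != "none" for s in subjects) == 9
        assert all(
            (s.group == "stroke") == (s.lesioned_hemisphere != "none")
            for s in subjects
        )
        # 18 subjects x 2 parameters x 3 regions x 2 sides
        assert len(samples) == 18 * 2 * 3 * 2

    def test_clinical_invariants(self, cohort):
        subjects, _ = cohort
        for s in subjects:
            assert 0 <= s.fm_ue_baseline <= 66
            assert 0 <= s.fm_ue_tp2 <= 66
            assert 2 < s.days_to_baseline_scan < 14
            if s.group == "stroke":
                assert s.fm_ue_baseline <= 50

    def test_seeded_determinism(self, small_config):
        subs1, samp1 = generate_cohort(small_config)
        subs2, samp2 = generate_cohort(small_config)
        assert subs1 == subs2
        for a, b in zip(samp1, samp2):
            np.testing.assert_array_equal(a.values, b.values)

    def test_no_effect_case(self):
        cfg = CohortConfig(
            parameters=(ODI,), delta_max=0.0, outcome_noise_sd=0.0,
            baseline_noise_sd=0.0, voxels_per_roi=400, seed=5,
        )
        subjects, samples = generate_cohort(cfg)
        for s in subjects:
            if s.group == "stroke":
                assert s.fm_ue_tp2 == round(cfg.outcome_intercept)
        mc_tol = 3 * ODI.spread / np.sqrt(cfg.voxels_per_roi) * np.sqrt(2)
        for s in subjects:
            assert abs(_mean_diff(samples, s.subject_id, "ODI")) < mc_tol

    @pytest.mark.parametrize("spec,sign", [(ODI, +1), (FA, -1), (AD, -1)])
    def test_effect_injection_matches_delta(self, spec, sign):
        cfg = CohortConfig(parameters=(spec,), voxels_per_roi=2000,
                           delta_max=0.1, seed=42)
        subjects, samples = generate_cohort(cfg)
        tol = 3 * spec.spread / np.sqrt(cfg.voxels_per_roi) * np.sqrt(2)
        for s in subjects:
            if s.group != "stroke":
                continue
            diff = _mean_diff(samples, s.subject_id, spec.name)
            assert diff == pytest.approx(sign * s.delta, abs=tol)

    def test_control_hemispheres_symmetric(self):
        """Mean control asymmetry converges to 0 across seeded cohorts."""
        diffs = []
        for seed in range(30):
            cfg = CohortConfig(parameters=(ODI,), voxels_per_roi=200, seed=seed)
            subjects, samples = generate_cohort(cfg)
            for s in subjects:
                if s.group == "control":
                    diffs.append(_mean_diff(samples, s.subject_id, "ODI"))
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(diffs.size)
        assert abs(diffs.mean()) < 3 * se

    def test_outcome_linkage_noiseless(self):
        cfg = CohortConfig(parameters=(ODI,), outcome_noise_sd=0.0,
                           voxels_per_roi=50, seed=9)
        subjects, _ = generate_cohort(cfg)
        stroke = [s for s in subjects if s.group == "stroke"]
        deltas = np.array([s.delta for s in stroke])
        tp2 = np.array([s.fm_ue_tp2 for s in stroke], dtype=float)
        r = np.corrcoef(deltas, tp2)[0, 1]
        assert r == pytest.approx(-1.0, abs=0.01)  # rounding to integer scores

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_stroke=0)
        with pytest.raises(ValueError):
            CohortConfig(voxel_dims=(1.0, -1.0, 1.0))
        with pytest.raises(ValueError):
            CohortConfig(outcome_noise_sd=-1.0)
        with pytest.raises(ValueError):
            ParameterSpec("bad", "gamma", 0.5, 0.1)

    def test_baseline_cap_warning(self):
        cfg = CohortConfig(parameters=(ODI,), baseline_intercept=60.0, seed=1)
        with pytest.warns(UserWarning, match="clamped"):
            subjects, _ = generate_cohort(cfg)
        assert all(s.fm_ue_baseline <= 50 for s in subjects if s.group == "stroke")

    def test_noise_sd_for_r2_round_trip(self):
        cfg = CohortConfig(parameters=(ODI,))
        sd = noise_sd_for_r2(cfg, 0.85)
        signal_var = (cfg.outcome_slope * cfg.delta_max) ** 2 / 12.0
        assert signal_var / (signal_var + sd**2) == pytest.approx(0.85)


class TestLabelVolume:
    def test_constructed_geometry(self):
        cfg = CohortConfig(grid_shape=(20, 20, 20), box_shape=(4, 4, 4))
        lv = generate_label_volume(cfg)
        codes = sorted(set(np.unique(lv.grid)) - {0})
        assert codes == [1, 2, 3, 4, 5, 6]
        for code in codes:
            assert int((lv.grid == code).sum()) == 64

    def test_mirror_symmetry(self, labels):
        flipped = labels.grid[::-1, :, :]
        left = labels.region_mask("PLIC", "left")
        right = labels.region_mask("PLIC", "right")
        np.testing.assert_array_equal(left, (flipped == labels.code("PLIC", "right")))
        assert left.sum() == right.sum()

    def test_grid_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            generate_label_volume(CohortConfig(grid_shape=(6, 6, 6), box_shape=(4, 4, 4)))


@pytest.fixture(scope="module")
def labels64():
    return generate_label_volume(CohortConfig(grid_shape=(20, 20, 20), box_shape=(4, 4, 4)))


class TestLesionMask:
    def test_zero_overlap(self, labels64):
        mask = generate_lesion_mask(labels64, "PLIC", "left", 0.0)
        assert not (mask.grid & labels64.region_mask("PLIC", "left")).any()

    def test_full_overlap(self, labels64):
        mask = generate_lesion_mask(labels64, "PLIC", "left", 1.0)
        region = labels64.region_mask("PLIC", "left")
        assert (mask.grid & region).sum() == region.sum()

    def test_quarter_overlap_is_exact(self, labels64):
        mask = generate_lesion_mask(labels64, "PLIC", "left", 0.25)
        assert int((mask.grid & labels64.region_mask("PLIC", "left")).sum()) == 16

    def test_margin_does_not_change_overlap(self, labels64):
        region = labels64.region_mask("PLIC", "right")
        bare = generate_lesion_mask(labels64, "PLIC", "right", 0.5)
        padded = generate_lesion_mask(labels64, "PLIC", "right", 0.5, margin=2)
        assert (padded.grid & region).sum() == (bare.grid & region).sum() == 32
        assert padded.grid.sum() > bare.grid.sum()

    def test_unknown_region_rejected(self, labels64):
        with pytest.raises(KeyError):
            generate_lesion_mask(labels64, "thalamus", "left", 0.5)
        with pytest.raises(ValueError):
            generate_lesion_mask(labels64, "PLIC", "left", 1.5)
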