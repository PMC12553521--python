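"""Synthetic cohort generator: telemetry, outcomes, defect volumes."""

import numpy as np
import pytest

from rehabmech.activity import daily_metrics, ActivityFeatures
from rehabmech.fe import hu_for_modulus, MINERALIZED_MODULUS_THRESHOLD
from rehabmech.healing import detect_bridging
from rehabmech.synthetic import (
    DEFAULT_PROFILES,
    CohortConfig,
    DefectVolumeSpec,
    GoldilocksParams,
    RehabProfile,
    goldilocks_mean,
    simulate_cohort,
    simulate_defect_volume,
    simulate_feature_cohort,
    simulate_outcome,
    simulate_telemetry,
)

MINERAL_HU = hu_for_modulus(MINERALIZED_MODULUS_THRESHOLD)


def _features(distance=500.0, rest=10.0):
    return ActivityFeatures(distance, 60.0, 10.0, 120.0, 0.3, rest)


class TestTelemetry:
    def test_zero_bout_rate_is_flat(self):
        prof = RehabProfile("sed", 2.0, 0.0, 60.0, 0.3, 0.05)
        days = simulate_telemetry(prof, 3, seed=5)
        for d in days:
            assert np.all(d.cum_distance == 0.0)

    def test_deterministic_per_seed(self):
        prof = DEFAULT_PROFILES["restricted"]
        a = simulate_telemetry(prof, 2, seed=9)
        b = simulate_telemetry(prof, 2, seed=9)
        for da, db in zip(a, b):
            assert np.array_equal(da.cum_distance, db.cum_distance)

    def test_nondecreasing_and_flat_outside_window(self):
        prof = DEFAULT_PROFILES["restricted"]
        (day,) = simulate_telemetry(prof, 1, seed=2)
        assert np.all(np.diff(day.cum_distance) >= 0)
        w0, w1 = prof.access_window
        assert day.cum_distance[w0 - 1] == 0.0
        # flat after the window closes
        assert day.cum_distance[-1] == pytest.approx(
            day.cum_distance[w1 + 1]
        )

    def test_renewal_mean_distance(self):
        # bout_rate 3/h, duration 120 s, speed 0.3 m/s, 2 h access:
        # expectation 3*2*120*0.3 = 216 m/day
        prof = RehabProfile("t", 2.0, 3.0, 120.0, 0.3, 0.0)
        days = simulate_telemetry(prof, 200, seed=7)
        dist = np.array(
            [float(d.cum_distance[-1]) for d in days]
        )
        se = dist.std(ddof=1) / np.sqrt(len(dist))
        assert abs(dist.mean() - 216.0) < 3 * se

    def test_metrics_recover_profile_means(self):
        prof = DEFAULT_PROFILES["restricted"]
        days = simulate_telemetry(prof, 200, seed=3)
        feats = [daily_metrics(d) for d in days]
        dist = np.array([f.distance for f in feats])
        bouts = np.array([f.bouts_per_day for f in feats])
        se_d = dist.std(ddof=1) / np.sqrt(dist.size)
        se_b = bouts.std(ddof=1) / np.sqrt(bouts.size)
        assert abs(dist.mean() - prof.expected_daily_distance) < 3 * se_d
        expected_bouts = prof.bout_rate * prof.daily_access_hours
        assert abs(bouts.mean() - expected_bouts) < 3 * se_b

    def test_nonpositive_days_rejected(self):
        with pytest.raises(ValueError):
            simulate_telemetry(DEFAULT_PROFILES["restricted"], 0, seed=1)


class TestGoldilocks:
    def test_maximum_at_optimal_distance(self):
        p = GoldilocksParams(noise_sd=0.0)
        at_opt, _ = simulate_outcome(_features(p.d_opt), p, seed=0)
        for d in (p.d_opt - 200, p.d_opt + 200, 50.0, 1400.0):
            bv, _ = simulate_outcome(_features(d), p, seed=0)
            assert bv <= at_opt

    def test_symmetry_about_optimum(self):
        p = GoldilocksParams(noise_sd=0.0)
        lo, _ = simulate_outcome(_features(p.d_opt - 150), p, seed=0)
        hi, _ = simulate_outcome(_features(p.d_opt + 150), p, seed=0)
        assert lo == pytest.approx(hi)

    def test_monotone_in_rest(self):
        p = GoldilocksParams(noise_sd=0.0)
        grid = np.linspace(0.5, 23.0, 40)
        vals = goldilocks_mean(600.0, grid, p)
        assert np.all(np.diff(vals) > 0)
        lo, _ = simulate_outcome(_features(rest=2.0), p, seed=0)
        hi, _ = simulate_outcome(_features(rest=10.0), p, seed=0)
        assert hi > lo

    def test_missing_features_rejected(self):
        f = _features()
        f.velocity = float("nan")
        with pytest.raises(ValueError):
            simulate_outcome(f, GoldilocksParams(), seed=0)


class TestDefectVolume:
    def _spec(self, **kw):
        base = dict(
            grid_shape=(16, 16, 20), voxel_size=0.3, defect_length=3.0,
            intensity_noise_sd=0.0, seed=4,
        )
        base.update(kw)
        return DefectVolumeSpec(**base)

    def _mineral_mask(self, vol):
        return vol.intensities > MINERAL_HU

    def test_no_bridge_without_column(self):
        spec = self._spec(bridging_fraction=0.0, ectopic_fraction=0.4)
        vol = simulate_defect_volume(spec)
        assert not detect_bridging(self._mineral_mask(vol), spec.gap_slices)

    def test_full_column_bridges(self):
        spec = self._spec(bridging_fraction=1.0)
        vol = simulate_defect_volume(spec)
        assert detect_bridging(self._mineral_mask(vol), spec.gap_slices)

    def test_mineral_count_increases_with_bridging_fraction(self):
        counts = []
        for bf in (0.2, 0.5, 0.8):
            vol = simulate_defect_volume(self._spec(bridging_fraction=bf))
            z0, z1 = self._spec().gap_slices
            counts.append(
                int(self._mineral_mask(vol)[:, :, z0:z1].sum())
            )
        assert counts[0] < counts[1] < counts[2]

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            self._spec(grid_shape=(16, 16, 8))


class TestCohort:
    def test_default_cohort_is_13_subjects_6_unions(self):
        bundle = simulate_cohort(CohortConfig(seed=1, n_days=2))
        assert len(bundle.subjects) == 13
        assert sum(s.designed_union for s in bundle.subjects) == 6

    def test_rerun_identical_outcome_table(self):
        a = simulate_cohort(CohortConfig(seed=3, n_days=2)).outcome_table()
        b = simulate_cohort(CohortConfig(seed=3, n_days=2)).outcome_table()
        assert a.equals(b)

    def test_profile_ordinal_structure(self):
        # low-distance runs least; unrestricted rests least
        means = {}
        for name, prof in DEFAULT_PROFILES.items():
            days = simulate_telemetry(prof, 12, seed=17)
            feats = [daily_metrics(d) for d in days]
            means[name] = (
                np.mean([f.distance for f in feats]),
                np.mean([f.rest for f in feats]),
            )
        assert means["low_distance"][0] < means["restricted"][0]
        assert means["low_distance"][0] < means["unrestricted"][0]
        assert means["unrestricted"][1] < means["restricted"][1]
        assert means["unrestricted"][1] < means["low_distance"][1]

    def test_union_bridging_fraction_increases(self):
        bundle = simulate_cohort(CohortConfig(seed=0, n_days=2))
        for s in bundle.subjects:
            bf2 = s.defect_specs[2].bridging_fraction
            bf4 = s.defect_specs[4].bridging_fraction
            if s.designed_union:
                assert bf4 > bf2
            else:
                assert bf4 == bf2

    def test_feature_cohort_shape_and_determinism(self):
        a = simulate_feature_cohort(40, seed=5)
        b = simulate_feature_cohort(40, seed=5)
        assert a.equals(b)
        assert len(a) == 40
        assert set(a.columns) >= {"distance", "rest", "bone_volume", "union"}
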