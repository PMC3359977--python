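"""Generator behavior: reproducibility, confinement, and the qualitative
regimes each generator is built to reproduce."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from rpmkit import pairing as pr
from rpmkit import rpm
from rpmkit.simulate import (
    ACTIVITY_PRESETS,
    NucleusRenderConfig,
    SimulationConfig,
    isotropic_planar_tracks,
    render_nucleus,
    sample_vmf,
    simulate_collision_population,
    simulate_pairing_timecourse,
    simulate_tethered_track,
    simulate_tethered_tracks,
)


class TestTetheredTracks:
    def test_zero_motion_track_is_stationary(self):
        cfg = SimulationConfig(step_scale_um=0.0, dash_prob=0.0, loc_noise_um=0.0)
        t = simulate_tethered_track(cfg, seed=1)
        assert np.allclose(t.positions, t.positions[0])
        assert t.n_frames == cfg.n_frames

    def test_fixed_seed_is_bit_reproducible(self):
        cfg = SimulationConfig(step_scale_um=0.1, loc_noise_um=0.02, seed=42)
        a = simulate_tethered_track(cfg)
        b = simulate_tethered_track(cfg)
        assert np.array_equal(a.positions, b.positions)

    def test_confinement_to_projected_disc(self):
        cfg = SimulationConfig(
            nucleus_radius_um=0.9, step_scale_um=0.3, dash_prob=0.2, loc_noise_um=0.05
        )
        tracks = simulate_tethered_tracks(cfg, 50, seed=3)
        radius = max(np.linalg.norm(t.positions, axis=1).max() for t in tracks)
        assert radius <= cfg.nucleus_radius_um + 3 * cfg.loc_noise_um + 1e-9

    def test_memoryless_walk_has_no_turning_bias(self):
        cfg = SimulationConfig(persistence=0.0, step_scale_um=0.05)
        tracks = simulate_tethered_tracks(cfg, 2000, seed=4)
        mean_bias = np.mean([rpm.bias(t) for t in tracks])
        assert abs(mean_bias) < 0.02

    def test_persistence_extends_range_without_raising_speed(self):
        # raising directional persistence at fixed step scale grows the
        # bounding box while leaving the average step length untouched
        stats = {}
        for pers in (0.0, 0.6):
            cfg = SimulationConfig(step_scale_um=0.08, persistence=pers, n_frames=121)
            tracks = simulate_tethered_tracks(cfg, 1000, seed=5)
            stats[pers] = (
                np.median([rpm.bbox_area(t, 60) for t in tracks]),
                np.median([rpm.avg_speed(t) for t in tracks]),
            )
        assert stats[0.6][0] > stats[0.0][0]
        assert abs(stats[0.6][1] - stats[0.0][1]) / stats[0.0][1] < 0.05

    def test_area_monotone_in_step_scale(self):
        medians = []
        scales = [0.03, 0.06, 0.09, 0.12, 0.15]
        for s in scales:
            cfg = SimulationConfig(step_scale_um=s)
            tracks = simulate_tethered_tracks(cfg, 500, seed=6)
            medians.append(np.median([rpm.bbox_area(t, 60) for t in tracks]))
        rho, _ = spearmanr(scales, medians)
        assert rho > 0.9

    def test_activity_presets_are_strictly_ordered(self):
        medians = []
        for name, cfg in ACTIVITY_PRESETS.items():
            tracks = simulate_tethered_tracks(cfg, 500, seed=7)
            medians.append(np.median([rpm.bbox_area(t, 60) for t in tracks]))
        assert all(a > b for a, b in zip(medians, medians[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(step_scale_um=float("nan"))
        with pytest.raises(ValueError):
            SimulationConfig(persistence=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(dash_prob=1.5)


class TestIsotropicPlanarTracks:
    def test_expected_bias_is_zero(self):
        pos = isotropic_planar_tracks(5000, 120, 0.1, seed=8)
        mean_bias = np.mean([rpm.bias(rpm.SpotTrack(p)) for p in pos])
        assert abs(mean_bias) < 0.02

    def test_shape_and_origin(self):
        pos = isotropic_planar_tracks(3, 50, 0.1, seed=9)
        assert pos.shape == (3, 50, 2)
        assert np.array_equal(pos[:, 0], np.zeros((3, 2)))


class TestPairingTimecourse:
    def test_zero_rate_gives_constant_expectation(self):
        cfg = SimulationConfig()
        tc = simulate_pairing_timecourse(cfg, 10**6, [1, 3, 5, 7], 0.0, seed=10)
        assert np.ptp(tc.percent_paired) < 0.5

    def test_large_n_recovers_rate(self):
        cfg = SimulationConfig()
        tc = simulate_pairing_timecourse(cfg, 10**6, [3, 5], 10.0, seed=11)
        assert pr.pairing_rate(tc) == pytest.approx(10.0, abs=0.1)

    def test_estimator_unbiased_at_standard_scoring_depth(self, rng):
        # 200 scored cells per timepoint; mean estimate over many
        # replicates recovers the true ramp slope
        n, rate, reps = 200, 10.0, 2000
        p3, p5 = 0.20, 0.40
        est = (rng.binomial(n, p5, reps) - rng.binomial(n, p3, reps)) / n * 100 / 2
        assert abs(est.mean() - rate) < 0.2

    def test_empty_hours_rejected(self):
        with pytest.raises(ValueError):
            simulate_pairing_timecourse(SimulationConfig(), 100, [], 5.0)


class TestCollisionPopulation:
    def test_absorbing_trap_dominates_reversible(self):
        cfg_t = SimulationConfig(trap_mode="tetramer", step_scale_um=0.1)
        cfg_d = dataclasses.replace(cfg_t, trap_mode="dimer", unpair_rate_per_s=0.05)
        obs_t = simulate_collision_population(cfg_t, 400, 300, seed=12)
        obs_d = simulate_collision_population(cfg_d, 400, 300, seed=12)
        assert pr.paired_fraction(obs_t)[0] >= pr.paired_fraction(obs_d)[0]

    def test_reduced_activity_reduces_collisions(self):
        cfg = SimulationConfig(trap_mode="tetramer", step_scale_um=0.1)
        half = dataclasses.replace(cfg, step_scale_um=0.05)
        f_full = pr.paired_fraction(simulate_collision_population(cfg, 1000, 300, seed=13))[0]
        f_half = pr.paired_fraction(simulate_collision_population(half, 1000, 300, seed=13))[0]
        assert f_half < f_full

    def test_zero_duration_matches_chance_overlap(self):
        # for two uniform points on a sphere of radius R the probability of
        # separation < r is r²/(4R²)
        cfg = SimulationConfig(trap_mode="tetramer")
        obs = simulate_collision_population(cfg, 4000, 0, seed=14)
        frac = pr.paired_fraction(obs)[0]
        expected = 100 * cfg.capture_radius_um**2 / (4 * cfg.nucleus_radius_um**2)
        se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / 4000)
        assert abs(frac - expected) < 4 * se


class TestRenderNucleus:
    def test_cluster_at_spb_gives_coincident_centroids(self):
        from rpmkit import bouquet as bq

        cfg = NucleusRenderConfig(
            cluster_concentration=1e6, cluster_direction=(1, 0, 0), spb_direction=(1, 0, 0)
        )
        img = render_nucleus(cfg, seed=15)
        d = np.linalg.norm(
            bq.weighted_centroid(img, "TEL") - bq.weighted_centroid(img, "SPB")
        )
        assert d < 0.05  # sub-voxel

    def test_antipodal_cluster_sits_two_radii_away(self):
        from rpmkit import bouquet as bq

        cfg = NucleusRenderConfig(
            cluster_concentration=1e6, cluster_direction=(-1, 0, 0), spb_direction=(1, 0, 0)
        )
        img = render_nucleus(cfg, seed=16)
        d = np.linalg.norm(
            bq.weighted_centroid(img, "TEL") - bq.weighted_centroid(img, "SPB")
        )
        assert d == pytest.approx(2 * cfg.dapi_radius_um, abs=0.2)

    def test_uniform_foci_centroid_at_origin(self):
        from rpmkit import bouquet as bq

        cfg = NucleusRenderConfig(cluster_concentration=0.0, n_foci=10000)
        img = render_nucleus(cfg, seed=17)
        offset = bq.weighted_centroid(img, "TEL") - bq.weighted_centroid(img, "DNA")
        # s.e. of the mean of uniform surface points is R/sqrt(3 n) per axis
        assert np.all(np.abs(offset) < 3 * cfg.dapi_radius_um / np.sqrt(3 * 10000) + 0.02)

    def test_grid_covers_sphere_or_rejects(self):
        with pytest.raises(ValueError):
            NucleusRenderConfig(n_slices=8, z_step_um=0.2, dapi_radius_um=1.0)

    def test_render_is_seed_reproducible(self):
        cfg = NucleusRenderConfig(cluster_concentration=4.0, noise_sd=0.01, seed=18)
        assert np.array_equal(render_nucleus(cfg).voxels, render_nucleus(cfg).voxels)


class TestVonMisesFisher:
    def test_kappa_zero_is_uniform(self, rng):
        v = sample_vmf((0, 0, 1), 0.0, 20000, rng)
        assert np.allclose(np.linalg.norm(v, axis=1), 1.0)
        assert np.all(np.abs(v.mean(axis=0)) < 0.02)

    def test_large_kappa_concentrates_on_mean(self, rng):
        mu = np.array([1.0, 2.0, -0.5])
        mu /= np.linalg.norm(mu)
        v = sample_vmf(mu, 1e5, 500, rng)
        assert np.all(v @ mu > 0.999)

    def test_mean_resultant_increases_with_kappa(self, rng):
        mu = (0, 1, 0)
        resultants = [
            np.linalg.norm(sample_vmf(mu, k, 4000, rng).mean(axis=0))
            for k in (0.5, 2, 8, 32)
        ]
        assert all(a < b for a, b in zip(resultants, resultants[1:]))
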