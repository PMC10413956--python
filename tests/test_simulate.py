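"""Correlated-random-walk generator, mosaic geometry, line of sight."""

import numpy as np
import pytest

from foragepath.data import HABITAT_VEGETATION, validate_dataset, write_fixes_csv
from foragepath.paths import compute_steps, proportion_moving, straightness_index
from foragepath.simulate import (
    HabitatMosaic,
    SimulationConfig,
    SpeciesMovementParams,
    generate_dataset,
    generate_mosaic,
    line_of_sight,
    preset,
    simulate_observation,
)


def params(label="test", **kw):
    base = dict(p_move=0.6, step_mu_log=0.7, step_sigma_log=0.9,
                kappa_turn=0.8, cover_bias=0.0)
    base.update(kw)
    return SpeciesMovementParams(label=label, **base)


def open_mosaic(side=100.0):
    return HabitatMosaic(side=side, centers=np.empty((0, 2)),
                         radii=np.empty(0), plant_species=[])


class TestGenerateMosaic:
    def test_zero_patches_gives_open_arena(self):
        config = SimulationConfig(cover_fraction=0.0)
        m = generate_mosaic(config, seed=1)
        assert m.n_patches == 0
        assert m.vegetated_fraction() == 0.0

    def test_same_seed_identical_mosaic(self):
        config = SimulationConfig()
        a = generate_mosaic(config, seed=5)
        b = generate_mosaic(config, seed=5)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.radii, b.radii)
        assert a.plant_species == b.plant_species

    def test_degenerate_cover_rejected(self):
        with pytest.raises(ValueError):
            generate_mosaic(SimulationConfig(cover_fraction=0.9), seed=1)

    def test_union_area_matches_monte_carlo(self, rng):
        # exact union area (geometry library) vs point-in-patch sampling
        m = generate_mosaic(SimulationConfig(cover_fraction=0.15), seed=2)
        pts = rng.uniform(0.0, m.side, size=(20_000, 2))
        d2 = ((pts[:, None, :] - m.centers[None, :, :]) ** 2).sum(axis=2)
        inside = (d2 <= m.radii[None, :] ** 2).any(axis=1)
        assert m.vegetated_fraction() == pytest.approx(inside.mean(), abs=0.02)

    def test_patches_lie_inside_arena(self):
        m = generate_mosaic(SimulationConfig(), seed=3)
        assert np.all(m.centers - m.radii[:, None] >= 0.0)
        assert np.all(m.centers + m.radii[:, None] <= m.side)


class TestLineOfSight:
    def test_open_arena_always_clear(self, rng):
        m = open_mosaic()
        for _ in range(20):
            p0, p1 = rng.uniform(0, 100, size=(2, 2))
            assert line_of_sight(p0, p1, m)

    def test_patch_blocking_midpoint(self):
        m = HabitatMosaic(side=20.0, centers=np.array([[10.0, 10.0]]),
                          radii=np.array([1.0]), plant_species=["sage"])
        assert not line_of_sight((5.0, 10.0), (15.0, 10.0), m)

    def test_endpoint_patch_is_transparent(self):
        m = HabitatMosaic(side=20.0, centers=np.array([[5.0, 10.0]]),
                          radii=np.array([1.0]), plant_species=["sage"])
        # start inside the bush, look straight out through it
        assert line_of_sight((5.0, 10.0), (15.0, 10.0), m)

    def test_tangent_segment_is_clear(self):
        m = HabitatMosaic(side=20.0, centers=np.array([[10.0, 11.0]]),
                          radii=np.array([1.0]), plant_species=["sage"])
        # segment along y=10 touches the disc boundary without entering
        assert line_of_sight((5.0, 10.0), (15.0, 10.0), m)

    def test_agrees_with_dense_sampling(self, rng):
        # 500-case version of the acceptance-scale geometry check
        config = SimulationConfig(cover_fraction=0.12, arena_side=30.0)
        m = generate_mosaic(config, seed=9)
        for _ in range(500):
            p0, p1 = rng.uniform(0.0, 30.0, size=(2, 2))
            assert line_of_sight(p0, p1, m) == brute_force_los(p0, p1, m)


def brute_force_los(p0, p1, mosaic, spacing=0.01) -> bool:
    """1-cm discretization of the sight line: no sampled point strictly
    inside a non-endpoint patch."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d0 = np.hypot(*(mosaic.centers - p0).T)
    d1 = np.hypot(*(mosaic.centers - p1).T)
    consider = (d0 > mosaic.radii) & (d1 > mosaic.radii)
    if not consider.any():
        return True
    length = float(np.hypot(*(p1 - p0)))
    n = max(2, int(np.ceil(length / spacing)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    c = mosaic.centers[consider]
    r = mosaic.radii[consider]
    d2 = ((pts[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    return not bool(np.any(d2 < r[None, :] ** 2))


class TestSimulateObservation:
    def test_never_moving_animal_stays_put(self):
        obs = simulate_observation(params(p_move=0.0), open_mosaic(), 31, seed=4)
        xs = {(f.x, f.y) for f in obs.fixes}
        assert len(xs) == 1
        steps = compute_steps(obs)
        assert proportion_moving(steps) == 0.0

    def test_near_ballistic_limit_is_straight(self):
        hits = 0
        for seed in range(200):
            obs = simulate_observation(
                params(p_move=1.0, kappa_turn=200.0, step_mu_log=0.0,
                       step_sigma_log=0.3),
                open_mosaic(side=10_000.0), 31, seed=seed)
            if straightness_index(obs) > 0.95:
                hits += 1
        assert hits >= 190

    def test_proportion_moving_concentrates_at_p_move(self):
        moved = total = 0
        for seed in range(500):
            obs = simulate_observation(params(p_move=0.5), open_mosaic(), 31,
                                       seed=10_000 + seed)
            steps = compute_steps(obs)
            moved += sum(s.moved for s in steps)
            total += len(steps)
        assert moved / total == pytest.approx(0.5, abs=0.01)

    def test_fixes_stay_inside_arena(self):
        obs = simulate_observation(
            params(p_move=1.0, step_mu_log=2.5), open_mosaic(side=20.0), 31, seed=6)
        for f in obs.fixes:
            assert 0.0 <= f.x <= 20.0 and 0.0 <= f.y <= 20.0

    def test_habitat_labels_consistent_with_geometry(self):
        m = generate_mosaic(SimulationConfig(cover_fraction=0.2), seed=7)
        obs = simulate_observation(params(cover_bias=0.5), m, 31, seed=8)
        for f in obs.fixes:
            patch = m.containing_patch(f.x, f.y)
            if f.habitat == HABITAT_VEGETATION:
                assert patch is not None
                assert f.plant_species == m.plant_species[patch]
            else:
                assert patch is None and f.plant_species is None


class TestGenerateDataset:
    def test_field_scale_observation_count(self, field_scale_dataset):
        ds = field_scale_dataset
        assert len(ds.observations) == 112
        assert len(ds.by_species("visual")) == 61
        assert len(ds.by_species("chemosensory")) == 51
        assert validate_dataset(ds) == []

    def test_same_master_seed_byte_identical_csv(self, tmp_path):
        config = SimulationConfig(n_per_species={"visual": 6, "chemosensory": 6},
                                  master_seed=11)
        ps = [preset("visual"), preset("chemosensory")]
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_fixes_csv(generate_dataset(config, ps), a)
        write_fixes_csv(generate_dataset(config, ps), b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        ps = [preset("visual"), preset("chemosensory")]
        d1 = generate_dataset(SimulationConfig(
            n_per_species={"visual": 3, "chemosensory": 3}, master_seed=1), ps)
        d2 = generate_dataset(SimulationConfig(
            n_per_species={"visual": 3, "chemosensory": 3}, master_seed=2), ps)
        f1 = d1.observations[0].fixes
        f2 = d2.observations[0].fixes
        assert any((a.x, a.y) != (b.x, b.y) for a, b in zip(f1, f2))

    def test_duplicate_species_labels_rejected(self):
        config = SimulationConfig(n_per_species={"visual": 2})
        with pytest.raises(ValueError, match="duplicate"):
            generate_dataset(config, [preset("visual"), preset("visual")])

    def test_truncated_observations_have_10_to_30_fixes(self):
        config = SimulationConfig(n_per_species={"visual": 40},
                                  truncation_prob=0.5, master_seed=13)
        ds = generate_dataset(config, [preset("visual")])
        lengths = {len(o.fixes) for o in ds.observations}
        short = {n for n in lengths if n < 31}
        assert short and all(10 <= n <= 30 for n in short)

    def test_visibility_monotone_under_patch_removal(self, rng):
        # removing a patch can only open sight lines, never close them
        m = generate_mosaic(SimulationConfig(cover_fraction=0.25), seed=17)
        obs = simulate_observation(params(cover_bias=0.6), m, 31, seed=18)
        drop = rng.integers(0, m.n_patches)
        keep = np.arange(m.n_patches) != drop
        m2 = HabitatMosaic(side=m.side, centers=m.centers[keep],
                           radii=m.radii[keep],
                           plant_species=[s for i, s in enumerate(m.plant_species)
                                          if keep[i]])
        for a, b in zip(obs.fixes[:-1], obs.fixes[1:]):
            if b.visible_from_previous:
                assert line_of_sight((a.x, a.y), (b.x, b.y), m2)

    def test_weather_series_shared_across_observations(self):
        config = SimulationConfig(n_per_species={"visual": 4}, master_seed=19,
                                  truncation_prob=0.0)
        ds = generate_dataset(config, [preset("visual")])
        temps = {o.fixes[5].air_temp_c for o in ds.observations}
        assert len(temps) == 1
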