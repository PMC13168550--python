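"""Simulation engine: detection geometry, placement, visits, scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from occuhet import (
    Bird,
    ScenarioConfig,
    core_territory_area_ha,
    perceptibility,
    place_territories,
    sampling_radius,
    simulate_scenario,
    simulate_site,
    simulate_visit,
    site_occupied,
)
from occuhet.simulate import inhibition_radius


class TestPerceptibility:
    @pytest.mark.parametrize("d, edr, expected", [
        (50.0, 60.0, 0.4994),   # ~50% at 50 m
        (0.0, 60.0, 1.0),
        (100.0, 60.0, 0.0622),  # ~6% at 100 m
        (10.0, 60.0, 0.9726),   # ~97% at 10 m
    ])
    def test_half_normal_values(self, d, edr, expected):
        assert perceptibility(d, edr) == pytest.approx(expected, abs=1e-4)

    @given(st.floats(0.0, 500.0), st.floats(0.0, 500.0),
           st.floats(30.0, 200.0))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_nonincreasing(self, d1, d2, edr):
        lo, hi = sorted((d1, d2))
        assert perceptibility(hi, edr) <= perceptibility(lo, edr) <= 1.0
        assert perceptibility(hi, edr) > 0.0  # no underflow for d/edr < 27

    def test_invalid_edr_raises(self):
        with pytest.raises(ValueError):
            perceptibility(10.0, 0.0)
        with pytest.raises(ValueError):
            sampling_radius(-1.0)


class TestSamplingRadius:
    def test_matches_six_percent_threshold(self):
        r = sampling_radius(60.0)
        assert r == pytest.approx(100.0, abs=1.0)
        assert perceptibility(r, 60.0) == pytest.approx(0.06, abs=1e-9)

    def test_linear_in_edr(self):
        assert sampling_radius(120.0) == pytest.approx(2 * sampling_radius(60.0))

    def test_edr90_agrees_with_root_finder(self):
        # independent numeric inversion of the half-normal at 0.06
        root = optimize.brentq(lambda d: perceptibility(d, 90.0) - 0.06,
                               1.0, 1000.0)
        assert sampling_radius(90.0) == pytest.approx(root, abs=1e-6)


def test_core_territory_areas_match_movement_sds():
    # 2-SD core discs for the five movement levels: 0 to 12.57 ha
    areas = [core_territory_area_ha(s) for s in (0, 10, 25, 50, 100)]
    assert areas == pytest.approx([0.0, 0.1257, 0.7854, 3.1416, 12.566],
                                  abs=5e-3)


class TestPlacement:
    def test_zero_density_gives_no_birds(self, rng):
        cfg = ScenarioConfig(density=0.0)
        assert place_territories(cfg, rng) == []

    def test_poisson_abundance_mean(self, rng):
        # density 0.1/ha on 225 ha => mean 22.5
        cfg = ScenarioConfig(density=0.1, movement_sd=0.0)
        n = [len(place_territories(cfg, rng)) for _ in range(400)]
        se = np.sqrt(22.5 / len(n))
        assert np.mean(n) == pytest.approx(22.5, abs=4 * se)

    def test_inhibition_distance_respected(self, rng):
        cfg = ScenarioConfig(density=0.5, movement_sd=0.0)
        birds = place_territories(cfg, rng)
        nests = np.array([b.nest for b in birds])
        d = np.linalg.norm(nests[:, None] - nests[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= inhibition_radius(0.5)
        assert nests.min() >= 0 and nests.max() <= cfg.landscape_edge

    def test_exactly_one_mode(self, rng):
        cfg = ScenarioConfig(exactly_one=True, movement_sd=25.0)
        birds = place_territories(cfg, rng)
        assert len(birds) == 1


class TestSiteOccupied:
    def test_boundary_cases(self):
        cfg = ScenarioConfig(movement_sd=0.0, edr=60.0)
        c = cfg.center
        near = [Bird(c + [99.0, 0.0], 0.0)]
        far = [Bird(c + [151.0, 0.0], 25.0)]
        assert site_occupied(near, cfg)
        cfg25 = ScenarioConfig(movement_sd=25.0, edr=60.0)
        assert not site_occupied(far, cfg25)
        assert not site_occupied([], cfg)


class TestSimulateVisit:
    def test_no_birds_never_detects(self, rng):
        cfg = ScenarioConfig()
        assert simulate_visit([], cfg, rng).detected == 0

    @pytest.mark.parametrize("distance", [0.0, 50.0])
    def test_stationary_bird_matches_thinned_poisson(self, rng, distance):
        # detection prob of >=1 cue: 1 - exp(-nu * t * g(d))
        cfg = ScenarioConfig(movement_sd=0.0, n_visits=1)
        bird = Bird(cfg.center + [distance, 0.0], 0.0)
        n = 20_000
        hits = sum(simulate_visit([bird], cfg, rng).detected
                   for _ in range(n))
        expect = 1 - np.exp(-2.5 * perceptibility(distance, cfg.edr))
        se = np.sqrt(expect * (1 - expect) / n)
        assert hits / n == pytest.approx(expect, abs=3 * se)

    def test_two_stationary_birds_independent(self, rng):
        cfg = ScenarioConfig(movement_sd=0.0, n_visits=1)
        birds = [Bird(cfg.center + [30.0, 0.0], 0.0),
                 Bird(cfg.center + [-70.0, 0.0], 0.0)]
        n = 20_000
        hits = sum(simulate_visit(birds, cfg, rng).detected for _ in range(n))
        g = perceptibility(30.0, 60.0) + perceptibility(70.0, 60.0)
        expect = 1 - np.exp(-2.5 * g)
        se = np.sqrt(expect * (1 - expect) / n)
        assert hits / n == pytest.approx(expect, abs=3 * se)

    def test_cue_log_records_cues(self, rng):
        cfg = ScenarioConfig(movement_sd=0.0, cue_rate=2.0)
        bird = Bird(cfg.center.copy(), 0.0)
        rec = simulate_visit([bird], cfg, rng, collect_log=True)
        assert rec.cue_log is not None and len(rec.cue_log) > 0
        times = [t for t, *_ in rec.cue_log]
        assert all(0 <= t <= cfg.duration for t in times)
        # at the nest, distance ~ 0 so every logged cue is detected
        assert rec.detected == int(any(flag for *_, flag in rec.cue_log))

    def test_cue_count_poisson_moments(self, rng):
        cfg = ScenarioConfig(movement_sd=0.0, cue_rate=0.25)
        bird = Bird(cfg.center.copy(), 0.0)
        counts = [len(simulate_visit([bird], cfg, rng, collect_log=True).cue_log)
                  for _ in range(4000)]
        mean, var = np.mean(counts), np.var(counts)
        # Poisson(2.5): mean = variance = 2.5
        assert mean == pytest.approx(2.5, abs=3 * np.sqrt(2.5 / 4000))
        assert var == pytest.approx(2.5, abs=0.3)


class TestSimulateSite:
    def test_occupancy_guaranteed(self):
        cfg = ScenarioConfig(density=0.1, movement_sd=0.0, n_visits=2)
        for i in range(5):
            birds, records = simulate_site(cfg, np.random.SeedSequence(i))
            assert site_occupied(birds, cfg)
            assert len(records) == 2

    def test_exactly_one_stationary_within_sampling_range(self):
        cfg = ScenarioConfig(exactly_one=True, movement_sd=0.0, n_visits=2)
        for i in range(5):
            birds, _ = simulate_site(cfg, np.random.SeedSequence(i))
            assert len(birds) == 1
            d = np.linalg.norm(birds[0].nest - cfg.center)
            assert d < sampling_radius(cfg.edr)


class TestSimulateScenario:
    def test_occupied_fraction_and_zero_rows(self, small_config):
        h = simulate_scenario(small_config)
        assert h.z.sum() == round(small_config.psi * small_config.n_sites)
        assert (h.y[~h.z] == 0).all()
        assert np.array_equal(h.D, h.y.sum(axis=1))

    def test_determinism(self, small_config):
        h1 = simulate_scenario(small_config)
        h2 = simulate_scenario(small_config)
        assert np.array_equal(h1.y, h2.y)
        other = ScenarioConfig(**{**small_config.to_dict(), "seed": 8})
        assert not np.array_equal(h1.y, simulate_scenario(other).y)

    def test_detection_counts_match_binomial_mixture_oracle(self):
        # psi=1, exactly one stationary bird: nest uniform on the 100-m disc,
        # D | d ~ Binomial(N, 1 - exp(-2.5 g(d))); mix over f(d) = 2d/R^2
        cfg = ScenarioConfig(exactly_one=True, movement_sd=0.0, psi=1.0,
                             n_sites=400, n_visits=10, seed=3)
        h = simulate_scenario(cfg)
        R = sampling_radius(cfg.edr)
        N = cfg.n_visits

        def cell(k):
            return integrate.quad(
                lambda d: stats.binom.pmf(
                    k, N, 1 - np.exp(-2.5 * perceptibility(d, cfg.edr)))
                * 2 * d / R**2, 0, R)[0]

        pmf = np.array([cell(k) for k in range(N + 1)])
        pmf /= pmf.sum()
        observed = np.bincount(h.D, minlength=N + 1)
        # pool sparse cells for a valid chi-squared comparison
        exp_counts = pmf * cfg.n_sites
        pool = exp_counts >= 5
        obs_p, exp_p = observed[pool].astype(float), exp_counts[pool]
        if (~pool).any():
            obs_p = np.append(obs_p, observed[~pool].sum())
            exp_p = np.append(exp_p, exp_counts[~pool].sum())
        exp_p *= obs_p.sum() / exp_p.sum()
        stat, p = stats.chisquare(obs_p, exp_p)
        assert p > 0.001
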