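import numpy as np
import pytest

from mucofilm import motility
from mucofilm.agents import Population
from mucofilm.scenario_config import (CryptGeometry, ScenarioConfig,
                                      SoluteSpec, SpeciesSpec,
                                      build_crypt_lattice)


def simple_config(**overrides):
    sp = [SpeciesSpec(name="green", kinetics={"A": (0.3, 0.2)}),
          SpeciesSpec(name="brown", kinetics={"A": (0.3, 0.2)})]
    defaults = dict(
        geometry=CryptGeometry(),
        solutes=[SoluteSpec(name="A", top_concentration=4.0)],
        species=sp, initial_counts={"green": 100, "brown": 100})
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def make_pop(cfg):
    return Population(cfg.geometry.width, cfg.geometry.height, cfg.species)


class TestTurnAngles:
    def test_mean_absolute_turn_is_45_degrees(self, rng):
        """Monte-Carlo check of the angle sampler: E|turn| = 45 deg."""
        draws = motility.turn_angle(rng, size=100_000)
        assert np.rad2deg(np.abs(draws).mean()) == pytest.approx(45.0, abs=1.0)
        # sign-symmetric
        assert abs(np.mean(np.sign(draws))) < 0.02

    def test_exponential_variant_same_mean(self, rng):
        draws = motility.turn_angle(rng, size=100_000,
                                    distribution="exponential")
        assert np.rad2deg(np.abs(draws).mean()) == pytest.approx(45.0, abs=1.0)


class TestSeeding:
    def test_exact_split_and_counts(self, rng):
        cfg = simple_config(placement_pattern="alternating")
        pop = make_pop(cfg)
        band = motility.release_band(cfg, None)
        ids = motility.seed_planktonic(pop, cfg, cfg.initial_counts, band, rng)
        assert ids.size == 200
        counts = np.bincount(pop.species_idx)
        assert list(counts) == [100, 100]
        # alternating pattern interleaves the two species
        assert list(pop.species_idx[:4]) == [0, 1, 0, 1]
        assert not pop.attached.any()
        assert np.all((pop.y >= band[0]) & (pop.y <= band[1]))

    def test_zero_count_adds_nothing(self, rng):
        cfg = simple_config()
        pop = make_pop(cfg)
        ids = motility.seed_planktonic(pop, cfg, {"green": 0}, (300, 480), rng)
        assert ids.size == 0

    def test_release_band_above_pillars(self):
        cfg = simple_config()
        lo, hi = motility.release_band(cfg, None)
        assert lo == pytest.approx(90.0 + 200.0)
        assert hi < cfg.geometry.height

    def test_x_positions_uniform(self):
        """Empirical CDF of x over 10^4 seeded agents is within Kolmogorov
        distance 0.02 of uniform."""
        from scipy import stats

        cfg = simple_config()
        pop = make_pop(cfg)
        rng = np.random.default_rng(7)
        motility.seed_planktonic(pop, cfg, {"green": 10_000}, (300, 480), rng)
        ks = stats.kstest(pop.x / cfg.geometry.width, "uniform")
        assert ks.statistic < 0.02


class TestRunAndTumble:
    def test_free_space_displacement_length(self, crypt_lattice, rng):
        """One 1 s step at 10 um/s displaces the cell by exactly 10 um."""
        cfg = simple_config()
        pop = make_pop(cfg)
        pop.add(0, 250.0, 400.0, 1.0, heading=0.3)
        x0, y0 = pop.x[0], pop.y[0]
        attached = motility.run_and_tumble_step(pop, 0, 1.0, rng,
                                                crypt_lattice, cfg)
        assert not attached
        assert pop.distance((x0, y0), (pop.x[0], pop.y[0])) == \
            pytest.approx(10.0, abs=1e-9)

    def test_contact_with_attached_agent_attaches(self, crypt_lattice, rng):
        """An agent already touching an attached cell attaches immediately,
        whatever direction its next run takes."""
        cfg = simple_config()
        pop = make_pop(cfg)
        pop.add(0, 250.0, 91.0, 1.0, attached=True)
        pop.add(0, 250.0, 92.0, 1.0)  # exactly in contact (r1 + r2 = 1)
        attached = motility.run_and_tumble_step(pop, 1, 1.0, rng,
                                                crypt_lattice, cfg)
        assert attached
        assert pop.attached[1]
        gap = pop.distance((pop.x[0], pop.y[0]), (pop.x[1], pop.y[1]))
        assert gap == pytest.approx(pop.radius[0] + pop.radius[1], abs=1e-6)

    def test_approach_halts_at_first_contact(self, crypt_lattice):
        """A run carrying the cell through an attached cell stops at the
        first point of contact instead."""
        cfg = simple_config()
        pop = make_pop(cfg)
        pop.add(0, 250.0, 91.0, 1.0, attached=True)
        pop.add(0, 250.0, 95.0, 1.0)
        found = False
        for seed in range(40):  # find a draw whose turn aims downwards
            p = make_pop(cfg)
            p.add(0, 250.0, 91.0, 1.0, attached=True)
            p.add(0, 250.0, 95.0, 1.0, heading=-np.pi / 2)
            r = np.random.default_rng(seed)
            if motility.run_and_tumble_step(p, 1, 1.0, r, crypt_lattice, cfg):
                gap = p.distance((p.x[0], p.y[0]), (p.x[1], p.y[1]))
                assert gap == pytest.approx(p.radius[0] + p.radius[1],
                                            abs=1e-6)
                found = True
                break
        assert found

    def test_substratum_contact_attaches_tangent(self, crypt_lattice):
        cfg = simple_config()
        pop = make_pop(cfg)
        pop.add(0, 35.0, 15.0, 1.0, heading=-np.pi / 2)  # between pillars
        rng = np.random.default_rng(0)
        motility.run_and_tumble_step(pop, 0, 1.0, rng, crypt_lattice, cfg)
        assert pop.attached[0]
        assert pop.y[0] == pytest.approx(10.0 + pop.radius[0], abs=1e-6)

    def test_attachment_is_absorbing(self, crypt_lattice, rng):
        cfg = simple_config()
        pop = make_pop(cfg)
        pop.add(0, 250.0, 91.0, 1.0, attached=True)
        with pytest.raises(ValueError):
            motility.run_and_tumble_step(pop, 0, 1.0, rng, crypt_lattice, cfg)


class TestPlanktonicPhase:
    def test_phase_attaches_most_agents_deterministically(self):
        cfg = simple_config(seed=3)
        lat = build_crypt_lattice(cfg.geometry)
        pop = make_pop(cfg)
        rng = np.random.default_rng(3)
        ids = motility.seed_planktonic(pop, cfg, {"green": 50, "brown": 50},
                                       (100, 250), rng)
        n = motility.run_planktonic_phase(pop, ids, cfg, lat, rng)
        assert n == pop.attached.sum()
        assert n > 50  # most of a cohort released near the surface lands
        # attached cells rest on the surface or on other cells, never inside
        from mucofilm import mechanics

        d = mechanics.distance_to_solid(pop.x[pop.attached],
                                        pop.y[pop.attached], lat)
        assert np.all(d >= pop.radius[pop.attached] - 1e-5)

    def test_biomass_gain_under_one_percent(self):
        """Metabolism runs during the 100 s attachment phase under the
        usual rules, but the total biomass gain stays below 1%."""
        import mucofilm as mf
        from mucofilm import metabolism

        cfg = simple_config(seed=5, end_time=0.0)
        cfg.initial_counts = {"green": 30, "brown": 30}
        sim = mf.Simulation(cfg)
        band = motility.release_band(cfg, sim.lattice)
        ids = motility.seed_planktonic(sim.pop, cfg, cfg.initial_counts, band,
                                       sim.rng["placement"])
        m0 = sim.pop.mass.sum()
        motility.run_planktonic_phase(sim.pop, ids, cfg, sim.lattice,
                                      sim.rng["motility"])
        fields = sim._solve_fields()
        metabolism.grow_step(sim.pop, fields, 100 / 3600.0,
                             include_floating=True,
                             biomass_to_substrate=cfg.biomass_to_substrate)
        gain = sim.pop.mass.sum() / m0 - 1.0
        assert 0.0 < gain < 0.01
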