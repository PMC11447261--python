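import numpy as np
import pytest

from mucofilm import metabolism, solute_transport as st
from mucofilm.agents import Population
from mucofilm.scenario_config import CryptGeometry, SoluteSpec, SpeciesSpec


def species_a(**kw):
    return SpeciesSpec(name="green", kinetics={"A": (0.3, 0.2)}, **kw)


class TestMonod:
    def test_zero_substrate(self):
        assert metabolism.monod_mu(0.0, 0.3, 0.2) == 0.0

    def test_half_saturation(self):
        assert metabolism.monod_mu(0.2, 0.3, 0.2) == pytest.approx(0.15)

    def test_saturation_limit(self):
        assert metabolism.monod_mu(0.2 * 1e6, 0.3, 0.2) == \
            pytest.approx(0.3, abs=1e-5)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            metabolism.monod_mu(-0.1, 0.3, 0.2)


class TestTotalGrowthRate:
    def test_single_substrate_saturated(self):
        assert metabolism.total_growth_rate(species_a(), {"A": 1e9}) == \
            pytest.approx(0.3, abs=1e-6)

    def test_mutualist_additive_uptake(self):
        sp = SpeciesSpec(name="m", kinetics={"A": (0.3, 0.2), "C": (0.3, 0.2)})
        mu = metabolism.total_growth_rate(sp, {"A": 1e9, "C": 1e9})
        assert mu == pytest.approx(0.6, abs=1e-5)

    def test_no_substrate_zero(self):
        assert metabolism.total_growth_rate(species_a(), {"A": 0.0}) == 0.0


def uniform_fields(lattice, value, name="A"):
    solute = SoluteSpec(name=name, top_concentration=value)
    conc = {name: np.full((lattice.nx, lattice.ny), float(value))}
    d = {name: np.full((lattice.nx, lattice.ny), solute.d_bulk)}
    codes = np.where(lattice.solid, st.SOLID, st.FLUID).astype(np.int8)
    return st.SoluteField(lattice=lattice, solutes=[solute],
                          concentrations=conc, codes=codes, diffusivity=d)


class TestGrowStep:
    def make(self, flat_lattice, s_value, m=0.03):
        pop = Population(100, 100, [species_a(maintenance=m)])
        pop.add(0, 50.0, 15.0, 1.0, attached=True)
        return pop, uniform_fields(flat_lattice, s_value)

    def test_euler_arithmetic(self, flat_lattice):
        """x=1, mu=0.3 (saturating S), m=0.03, dt=0.25 h -> x = 1.0675."""
        pop, fields = self.make(flat_lattice, 1e9)
        metabolism.grow_step(pop, fields, 0.25)
        assert pop.mass[0] == pytest.approx(1.0675, abs=1e-6)

    def test_balance_point_mass_unchanged(self, flat_lattice):
        # choose S so that mu == m: mu = mumax*S/(S+Ks) = 0.03 -> S = 0.2/9
        pop, fields = self.make(flat_lattice, 0.2 / 9)
        metabolism.grow_step(pop, fields, 0.25)
        assert pop.mass[0] == pytest.approx(1.0, abs=1e-12)

    def test_starvation_maintenance_decay(self, flat_lattice):
        pop, fields = self.make(flat_lattice, 0.0)
        metabolism.grow_step(pop, fields, 0.25)
        assert pop.mass[0] == pytest.approx(1 - 0.03 * 0.25)

    def test_bookkeeping_yield_consistency(self, flat_lattice, rng):
        """Sum of biomass increments equals Y times substrate consumed minus
        maintenance losses."""
        pop = Population(100, 100, [species_a()])
        pop.add(np.zeros(30, dtype=np.int32), rng.uniform(0, 100, 30),
                rng.uniform(11, 40, 30), rng.uniform(0.5, 2.0, 30),
                attached=True)
        fields = uniform_fields(flat_lattice, 0.7)
        mass0 = pop.mass.copy()
        res = metabolism.grow_step(pop, fields, 0.25, biomass_to_substrate=1.0)
        maint = float(np.sum(0.03 * mass0 * 0.25))
        assert res.delta_mass.sum() == pytest.approx(
            0.15 * res.consumed["A"] - maint, rel=1e-9)

    def test_consumed_consistent_with_reaction_assembly(self, flat_lattice):
        """Per-step consumption equals the assembled block reaction rates at
        the same concentrations, times dt and block volume."""
        pop = Population(100, 100, [species_a()])
        pop.add(np.zeros(5, dtype=np.int32), [5.0, 15.0, 15.0, 42.0, 77.0],
                [15.0, 15.0, 25.0, 33.0, 15.0], [1.0, 2.0, 0.5, 1.5, 1.0],
                attached=True)
        fields = uniform_fields(flat_lattice, 0.9)
        biomass = st.biomass_by_block(pop, flat_lattice)
        res = metabolism.grow_step(pop, fields, 0.25, biomass_to_substrate=3.0)
        asm = st.assemble_reactions(biomass, fields.concentrations, pop.species,
                                    flat_lattice, biomass_to_substrate=3.0)
        vol = st.block_volume(flat_lattice)
        assert res.consumed["A"] == pytest.approx(
            asm.consumption["A"].sum() * vol * 0.25, rel=1e-9)

    def test_invalid_dt_rejected(self, flat_lattice):
        pop, fields = self.make(flat_lattice, 1.0)
        with pytest.raises(ValueError):
            metabolism.grow_step(pop, fields, 0.0)


class TestDivision:
    def test_below_threshold_no_division(self, rng):
        pop = Population(100, 100, [species_a()])
        pop.add(0, 50.0, 50.0, 1.5, attached=True, division_threshold=2.0)
        assert metabolism.divide(pop, rng) == 0
        assert len(pop) == 1

    def test_split_conserves_mass_and_places_tangent(self, rng):
        pop = Population(100, 100, [species_a()])
        pop.add(0, 50.0, 50.0, 2.0, attached=True, division_threshold=2.0)
        n = metabolism.divide(pop, rng)
        assert n == 1
        assert len(pop) == 2
        assert pop.mass.sum() == pytest.approx(2.0)
        assert pop.mass[0] == pytest.approx(1.0)
        gap = pop.distance((pop.x[0], pop.y[0]), (pop.x[1], pop.y[1]))
        assert gap == pytest.approx(pop.radius[0] + pop.radius[1], abs=1e-9)
        # both redraw thresholds within the truncated band
        assert np.all(pop.division_threshold >= 1.6)
        assert np.all(pop.division_threshold <= 2.4)

    def test_threshold_sampler_statistics(self, rng):
        draws = metabolism.draw_division_thresholds(10_000, rng)
        assert draws.mean() == pytest.approx(2.0, abs=0.01)
        assert np.all((draws >= 1.6) & (draws <= 2.4))

    def test_initial_mass_sampler(self, rng):
        draws = metabolism.draw_initial_masses(10_000, rng)
        assert draws.mean() == pytest.approx(1.0, abs=0.005)
        assert np.all((draws >= 0.8) & (draws <= 1.2))

    def test_daughter_not_placed_inside_wall(self, flat_lattice):
        pop = Population(100, 100, [species_a()])
        pop.add(0, 50.0, 10.8, 2.1, attached=True, division_threshold=2.0)
        for seed in range(10):
            p = Population(100, 100, [species_a()])
            p.add(0, 50.0, 10.8, 2.1, attached=True, division_threshold=2.0)
            metabolism.divide(p, np.random.default_rng(seed), flat_lattice)
            from mucofilm.mechanics import distance_to_solid

            d = distance_to_solid(p.x, p.y, flat_lattice)
            assert np.all(d >= 0)  # centers never inside solid
            assert p.y.min() >= 10.0  # above the base surface


class TestExponentialGrowthLimit:
    def test_unlimited_single_species_tracks_closed_form(self):
        """Without diffusion limitation the population biomass follows
        exp((mu - m) t) within 5% over 10 h."""
        import mucofilm as mf
        from mucofilm.scenario_config import ScenarioConfig

        cfg = ScenarioConfig(
            geometry=CryptGeometry(width=100, height=100, pillar_height=0),
            solutes=[SoluteSpec(name="A", top_concentration=4.0)],
            species=[species_a()],
            initial_counts={"green": 20},
            biomass_to_substrate=1.0,  # negligible consumption: no gradient
            growth_timestep=0.1,  # keep the Euler discretization error small
            end_time=10.0, seed=11)
        res = mf.run(cfg, seed=11)
        ts = res.timeseries
        m0 = ts.biomass.iloc[0]
        mu_eff = 0.3 * 4.0 / 4.2 - 0.03
        expect = m0 * np.exp(mu_eff * ts.time)
        ratio = ts.biomass / expect
        assert np.all(np.abs(ratio - 1.0) < 0.05)
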