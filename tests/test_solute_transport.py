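import numpy as np
import pytest

from mucofilm import fixtures, solute_transport as st
from mucofilm.agents import Population
from mucofilm.scenario_config import SoluteSpec, SpeciesSpec


def one_species():
    return [SpeciesSpec(name="green", kinetics={"A": (0.3, 0.2)})]


def bulk_a(**kw):
    return SoluteSpec(name="A", top_concentration=4.0, **kw)


class TestClassifyBlocks:
    def test_empty_domain_all_fluid(self, flat_lattice):
        codes = st.classify_blocks(None, flat_lattice)
        assert np.all(codes[:, 0] == st.SOLID)
        assert np.all(codes[:, 1:] == st.FLUID)

    def test_single_agent_marks_its_block(self, flat_lattice):
        pop = Population(100, 100, one_species())
        pop.add(0, 5.0, 15.0, 1.0, attached=True)
        codes = st.classify_blocks(pop, flat_lattice)
        assert codes[0, 1] == st.BIOFILM
        assert (codes == st.BIOFILM).sum() == 1

    def test_binning_matches_brute_force(self, flat_lattice, rng):
        pop = Population(100, 100, one_species())
        pop.add(np.zeros(200, dtype=np.int32), rng.uniform(0, 100, 200),
                rng.uniform(10, 100, 200), 1.0, attached=True)
        codes = st.classify_blocks(pop, flat_lattice)
        brute = np.zeros((10, 10), dtype=bool)
        for x, y in zip(pop.x, pop.y):
            brute[int(x // 10) % 10, min(int(y // 10), 9)] = True
        assert np.array_equal(codes == st.BIOFILM, brute & ~flat_lattice.solid)


class TestAssembleReactions:
    def test_no_agents_zero_reaction(self, flat_lattice):
        biomass = np.zeros((1, 10, 10))
        conc = {"A": np.full((10, 10), 4.0)}
        asm = st.assemble_reactions(biomass, conc, one_species(), flat_lattice,
                                    biomass_to_substrate=1.0)
        assert np.all(asm.net("A") == 0)

    def test_half_saturation_consumption(self, flat_lattice):
        """At S = Ks the Monod factor is 1/2, so one unit of biomass eats
        (1/0.15)*0.15 = 1 mass unit per hour per block volume."""
        biomass = np.zeros((1, 10, 10))
        biomass[0, 4, 2] = 1.0
        conc = {"A": np.full((10, 10), 0.2)}
        asm = st.assemble_reactions(biomass, conc, one_species(), flat_lattice,
                                    biomass_to_substrate=1.0)
        vol = st.block_volume(flat_lattice)
        assert asm.consumption["A"][4, 2] == pytest.approx(1.0 / vol)
        assert asm.consumption["A"].sum() == pytest.approx(1.0 / vol)

    def test_mutualism_pair_net_rate(self, flat_lattice):
        """Net by-product rate in a shared block equals production from the
        precursor minus the partner's consumption, hand-computed."""
        sp1 = SpeciesSpec(name="green", kinetics={"A": (0.3, 0.2)},
                          productions={"A": ("C", 0.85)})
        sp2 = SpeciesSpec(name="brown", kinetics={"C": (0.3, 0.2)})
        biomass = np.zeros((2, 10, 10))
        biomass[0, 3, 3] = 2.0
        biomass[1, 3, 3] = 1.5
        sa, c = 1.0, 0.4
        conc = {"A": np.full((10, 10), sa), "C": np.full((10, 10), c)}
        asm = st.assemble_reactions(biomass, conc, [sp1, sp2], flat_lattice,
                                    biomass_to_substrate=1.0)
        vol = st.block_volume(flat_lattice)
        prod = 0.85 * (0.3 / 0.15) * sa / (sa + 0.2) * 2.0 / vol
        cons = (0.3 / 0.15) * c / (c + 0.2) * 1.5 / vol
        assert asm.net("C")[3, 3] == pytest.approx(prod - cons)

    def test_negative_biomass_rejected(self, flat_lattice):
        with pytest.raises(ValueError):
            st.assemble_reactions(np.full((1, 10, 10), -1.0),
                                  {"A": np.zeros((10, 10))}, one_species(),
                                  flat_lattice, 1.0)


class TestSolveSteadyState:
    def test_no_reaction_gives_uniform_field(self, crypt_lattice):
        """With no sinks the harmonic problem with one Dirichlet value is
        the constant Sb everywhere in the fluid."""
        field = st.solve_steady_state(crypt_lattice, [bulk_a()], [],
                                      np.zeros((0, 50, 50)))
        s = field.concentrations["A"]
        nonsolid = field.codes != st.SOLID
        assert np.allclose(s[nonsolid], 4.0, atol=1e-9)

    def test_parabolic_column_profile(self):
        """Uniform zeroth-order sink in a closed-bottom column: discrete
        solution matches S(y) = Sb - (r0/2D)(H^2 - y^2) to O(h^2)."""
        prob = fixtures.make_column_problem(25, sink_rate=1.0, sb=4.0, d=1e4)
        species, biomass = prob.as_transport_inputs()
        field = st.solve_steady_state(prob.lattice, [prob.solute], species,
                                      biomass, biomass_to_substrate=1.0)
        got = field.concentrations["S"][0]
        expect = prob.analytic(prob.cell_centers())
        h = prob.lattice.block_size
        # truncation error scale: (r0/2D) h^2
        tol = 5 * prob.r0 / (2 * prob.d) * h ** 2
        assert np.max(np.abs(got - expect)) < tol

    def test_column_matches_independent_tridiagonal_oracle(self):
        prob = fixtures.make_column_problem(20, sink_rate=1.0, sb=4.0, d=1e4)
        species, biomass = prob.as_transport_inputs()
        field = st.solve_steady_state(prob.lattice, [prob.solute], species,
                                      biomass, biomass_to_substrate=1.0)
        oracle = fixtures.solve_column(prob)
        assert np.allclose(field.concentrations["S"][0], oracle, atol=1e-4)

    def test_refinement_reduces_error(self):
        errs = []
        for nblocks, h in ((10, 10.0), (20, 5.0)):
            prob = fixtures.make_column_problem(nblocks, sink_rate=2.0,
                                                sb=4.0, d=1e4, block_size=h)
            species, biomass = prob.as_transport_inputs()
            field = st.solve_steady_state(prob.lattice, [prob.solute], species,
                                          biomass, biomass_to_substrate=1.0)
            expect = prob.analytic(prob.cell_centers())
            errs.append(np.max(np.abs(field.concentrations["S"][0] - expect)))
        assert errs[1] < errs[0]

    def test_conservation_top_flux_equals_net_consumption(self, flat_lattice):
        """At convergence the diffusive influx across the top boundary
        balances consumption minus production over the domain."""
        sp = SpeciesSpec(name="green", kinetics={"A": (0.3, 0.2)},
                         productions={"A": ("C", 0.85)})
        solutes = [bulk_a(), SoluteSpec(name="C", top_concentration=0.0)]
        biomass = np.zeros((1, 10, 10))
        biomass[0, 2:5, 1] = 2e4
        biomass[0, 7, 1:3] = 1e4
        field = st.solve_steady_state(flat_lattice, solutes, [sp], biomass,
                                      biomass_to_substrate=1.0)
        asm = st.assemble_reactions(biomass, field.concentrations, [sp],
                                    flat_lattice, biomass_to_substrate=1.0)
        vol = st.block_volume(flat_lattice)
        for name in ("A", "C"):
            net_sink = (asm.consumption[name].sum()
                        - asm.production[name].sum()) * vol
            assert field.top_influx(name) == pytest.approx(net_sink, rel=1e-4)

    def test_pure_consumption_bounded_by_bulk(self, flat_lattice):
        biomass = np.zeros((1, 10, 10))
        biomass[0, :, 1] = 5e4
        field = st.solve_steady_state(flat_lattice, [bulk_a()], one_species(),
                                      biomass, biomass_to_substrate=1.0)
        s = field.concentrations["A"]
        nonsolid = field.codes != st.SOLID
        assert np.all(s[nonsolid] >= 0)
        assert np.all(s[nonsolid] <= 4.0 + 1e-9)

    def test_strong_sink_drives_interior_to_zero(self, flat_lattice):
        """In the strong-sink limit the biofilm blocks approach S = 0 and
        the boundary influx equals total consumption."""
        sp = [SpeciesSpec(name="green", kinetics={"A": (0.3, 1e-4)})]
        biomass = np.zeros((1, 10, 10))
        biomass[0, :, 1] = 1e7
        field = st.solve_steady_state(flat_lattice, [bulk_a()], sp, biomass,
                                      biomass_to_substrate=1.0, rtol=1e-12)
        s = field.concentrations["A"]
        assert np.max(s[:, 1]) < 1e-3
        asm = st.assemble_reactions(biomass, field.concentrations, sp,
                                    flat_lattice, biomass_to_substrate=1.0)
        total_cons = asm.consumption["A"].sum() * st.block_volume(flat_lattice)
        assert field.top_influx("A") == pytest.approx(total_cons, rel=1e-3)

    def test_host_source_pins_surface_blocks(self, crypt_lattice):
        host = SoluteSpec(name="H", top_concentration=0.0,
                          host_source_concentration=0.8)
        field = st.solve_steady_state(crypt_lattice, [host], [],
                                      np.zeros((0, 50, 50)))
        s = field.concentrations["H"]
        assert np.allclose(s[field.host_mask], 0.8)
        # decays away from the surface toward the zero top boundary
        assert s[25 // 10, -1] < 0.1

    def test_biofilm_diffusivity_reduced(self, flat_lattice):
        pop = Population(100, 100, one_species())
        pop.add(0, 15.0, 15.0, 1.0, attached=True)
        field = st.solve_steady_state(flat_lattice, [bulk_a()], one_species(),
                                      st.biomass_by_block(pop, flat_lattice),
                                      pop=pop)
        assert field.diffusivity["A"][1, 1] == pytest.approx(0.8 * bulk_a().d_bulk)
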