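"""Simulation driver: attachment phase, growth loop, events, output.

The growth loop executes, per timestep: pseudo-steady transport solve,
Monod growth, division, then mechanical relaxation (shoving + wall
constraints).  Planktonic episodes (the initial attachment phase and
scheduled invasions) run at the 1-second motility step with the same
metabolic rules.  A run is a pure function of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis, mechanics, metabolism, motility, solute_transport
from .agents import Population
from .scenario_config import ScenarioConfig, SubstratumLattice, build_crypt_lattice

log = logging.getLogger("mucofilm")


def thickness(pop: Population, lattice: SubstratumLattice,
              pillar_top: float | None = None) -> float:
    """Mean biofilm thickness above the pillar tops (um).

    Per block-resolution x-column: highest attached-agent y minus the
    pillar-top height, floored at zero; averaged over columns.  Returns
    0 when no agent is attached.
    """
    att = pop.attached
    if not att.any():
        return 0.0
    if pillar_top is None:
        pillar_top = motility.solid_top(lattice)
    b = lattice.block_size
    cols = (np.floor((pop.x[att] % pop.width) / b).astype(int) % lattice.nx)
    tops = np.zeros(lattice.nx)
    np.maximum.at(tops, cols, pop.y[att])
    heights = np.maximum(tops - pillar_top, 0.0)
    return float(heights.mean())


@dataclass
class Snapshot:
    time: float
    agents: pd.DataFrame
    concentrations: dict[str, np.ndarray]


@dataclass
class SimulationResult:
    config: ScenarioConfig
    lattice: SubstratumLattice
    population: Population
    timeseries: pd.DataFrame
    snapshots: list[Snapshot] = field(default_factory=list)
    fields: solute_transport.SoluteField | None = None
    n_floating: int = 0

    def final_abundance(self, basis: str = "biomass") -> dict[str, float]:
        return analysis.relative_abundance(self.population, basis=basis)

    def segregation(self, k: int = 8) -> analysis.SegregationResult:
        return analysis.segregation_index(self.population, k=k)


class Simulation:
    """Mutable simulation state; ``run()`` drives it to the end time."""

    def __init__(self, config: ScenarioConfig, seed: int | None = None):
        config.validate()
        self.config = config
        self.seed = config.seed if seed is None else seed
        root = np.random.SeedSequence(self.seed)
        # independent substreams so modules can be exercised in isolation
        keys = ("placement", "motility", "division", "mechanics")
        self.rng = {k: np.random.default_rng(s)
                    for k, s in zip(keys, root.spawn(len(keys)))}
        self.lattice = build_crypt_lattice(config.geometry)
        self.pop = Population(config.geometry.width, config.geometry.height,
                              config.species, r1=config.radius_unit_mass,
                              radius_scaling=config.radius_scaling)
        self.clock = 0.0  # h
        self.fields: solute_transport.SoluteField | None = None
        self.records: list[dict] = []
        self.snapshots: list[Snapshot] = []
        self._pillar_top = config.geometry.pillar_top

    # -- phases ------------------------------------------------------------

    def _planktonic(self, counts: dict[str, int], duration: float,
                    biofilm_top: float | None = None) -> int:
        cfg = self.config
        band = motility.release_band(cfg, self.lattice, biofilm_top=biofilm_top)
        ids = motility.seed_planktonic(self.pop, cfg, counts, band,
                                       self.rng["placement"])
        attached = motility.run_planktonic_phase(
            self.pop, ids, cfg, self.lattice, self.rng["motility"],
            duration=duration)
        # metabolism runs at the same rules during the phase; the net gain
        # over 100 s is well under 1% so a single lumped update suffices
        if self.fields is None:
            self.fields = self._solve_fields()
        metabolism.grow_step(self.pop, self.fields, duration / 3600.0,
                             include_floating=True,
                             biomass_to_substrate=cfg.biomass_to_substrate)
        log.info("planktonic phase: %d/%d attached", attached, len(ids))
        return attached

    def _solve_fields(self) -> solute_transport.SoluteField:
        cfg = self.config
        biomass = solute_transport.biomass_by_block(self.pop, self.lattice)
        initial = self.fields.concentrations if self.fields is not None else None
        return solute_transport.solve_steady_state(
            self.lattice, cfg.solutes, cfg.species, biomass, pop=self.pop,
            initial=initial, biomass_to_substrate=cfg.biomass_to_substrate)

    def _record(self) -> None:
        pop = self.pop
        rec: dict = {"time": self.clock,
                     "n_agents": len(pop),
                     "n_attached": pop.n_attached,
                     "thickness": thickness(pop, self.lattice, self._pillar_top)}
        att = pop.attached
        total_mass = float(pop.mass[att].sum()) if att.any() else 0.0
        rec["biomass"] = total_mass
        for i, sp in enumerate(pop.species):
            sel = att & (pop.species_idx == i)
            m = float(pop.mass[sel].sum())
            rec[f"biomass_{sp.name}"] = m
            rec[f"count_{sp.name}"] = int(sel.sum())
            rec[f"abundance_{sp.name}"] = m / total_mass if total_mass else np.nan
        self.records.append(rec)

    def _snapshot(self) -> None:
        conc = ({k: v.copy() for k, v in self.fields.concentrations.items()}
                if self.fields is not None else {})
        self.snapshots.append(Snapshot(time=self.clock,
                                       agents=self.pop.to_dataframe(),
                                       concentrations=conc))

    # -- main loop ---------------------------------------------------------

    def run(self, collect_snapshots: bool = False) -> SimulationResult:
        cfg = self.config
        dt = cfg.growth_timestep
        self._planktonic(cfg.initial_counts, cfg.attachment_duration)
        mechanics.relax(self.pop, self.lattice, cfg.shove_max_iters,
                        cfg.shove_tol, self.rng["mechanics"])
        self._record()
        if collect_snapshots:
            self.fields = self._solve_fields()
            self._snapshot()
        pending = sorted(cfg.invasions, key=lambda e: e.time)
        next_snap = cfg.output_cadence
        nsteps = int(round(cfg.end_time / dt))
        for step in range(1, nsteps + 1):
            t_next = step * dt
            while pending and pending[0].time <= t_next + 1e-9:
                ev = pending.pop(0)
                top = (float(self.pop.y[self.pop.attached].max())
                       if self.pop.n_attached else None)
                self._planktonic({ev.species: ev.count}, ev.duration,
                                 biofilm_top=top)
            self.fields = self._solve_fields()
            metabolism.grow_step(self.pop, self.fields, dt,
                                 biomass_to_substrate=cfg.biomass_to_substrate)
            ndiv = metabolism.divide(self.pop, self.rng["division"],
                                     self.lattice, cfg.division_split_cv)
            if ndiv:
                mechanics.relax(self.pop, self.lattice, cfg.shove_max_iters,
                                cfg.shove_tol, self.rng["mechanics"])
            self.clock = t_next
            self._record()
            if collect_snapshots and self.clock + 1e-9 >= next_snap:
                self._snapshot()
                next_snap += cfg.output_cadence
            if cfg.max_attached and self.pop.n_attached >= cfg.max_attached:
                log.info("agent cutoff reached at t=%.2f h", self.clock)
                break
            if (cfg.thickness_cap and
                    self.records[-1]["thickness"] >= cfg.thickness_cap):
                log.info("thickness cutoff reached at t=%.2f h", self.clock)
                break
        n_floating = int((~self.pop.attached).sum())
        return SimulationResult(
            config=cfg, lattice=self.lattice, population=self.pop,
            timeseries=pd.DataFrame(self.records), snapshots=self.snapshots,
            fields=self.fields, n_floating=n_floating)


def run(config: ScenarioConfig, seed: int | None = None,
        collect_snapshots: bool = False) -> SimulationResult:
    """Run one scenario to completion; a pure function of (config, seed)."""
    return Simulation(config, seed=seed).run(collect_snapshots=collect_snapshots)
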