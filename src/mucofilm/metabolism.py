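"""Per-agent Monod growth, maintenance, and cell division.

Growth follows saturating Monod kinetics, additively over every
substrate a species consumes; net biomass change per agent is
(mu_total - m) x per unit time, integrated with an explicit Euler step
at the block concentrations left by the transport solve.  Cells divide
once their mass crosses an individually drawn threshold (mean 2, 10%
CV, truncated at two standard deviations), splitting 50/50 with the
daughter placed tangent to the parent in a uniformly random direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import mechanics
from .scenario_config import SpeciesSpec, SubstratumLattice

MASS_FLOOR = 1e-6  # starved cells decay toward this, never below


def monod_mu(s, mumax: float, ks: float):
    """Monod growth rate mu = mumax * S / (Ks + S)."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("negative substrate concentration")
    if ks <= 0:
        raise ValueError("Ks must be positive")
    out = mumax * s / (ks + s)
    return float(out) if out.ndim == 0 else out


def total_growth_rate(species: SpeciesSpec, local_conc: dict[str, float]) -> float:
    """Additive Monod rate over every substrate the species consumes."""
    return float(sum(monod_mu(local_conc[sub], mu, ks)
                     for sub, (mu, ks) in species.kinetics.items()))


def truncated_normal(mean: float, cv: float, size, rng: np.random.Generator,
                     n_sigma: float = 2.0) -> np.ndarray:
    """Gaussian with the given coefficient of variation, resampled until
    every draw lies within ``n_sigma`` standard deviations of the mean."""
    sd = mean * cv
    out = rng.normal(mean, sd, size=size)
    bad = np.abs(out - mean) > n_sigma * sd
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = np.abs(out - mean) > n_sigma * sd
    return out


def draw_division_thresholds(size, rng: np.random.Generator) -> np.ndarray:
    """Division-mass thresholds: Normal(2, 0.2^2) truncated to [1.6, 2.4]."""
    return truncated_normal(2.0, 0.1, size, rng)


def draw_initial_masses(size, rng: np.random.Generator) -> np.ndarray:
    """Initial cell masses: Normal(1, 0.1^2) truncated to [0.8, 1.2]."""
    return truncated_normal(1.0, 0.1, size, rng)


@dataclass
class GrowthStepResult:
    """Per-step bookkeeping used by the engine and the audits."""

    mu_total: np.ndarray          # 1/h per agent (0 for floating agents)
    delta_mass: np.ndarray        # mass units per agent
    consumed: dict[str, float]    # substrate units per solute over the step
    produced: dict[str, float]


def grow_step(pop, fields, dt: float, *, include_floating: bool = False,
              biomass_to_substrate: float = 1.0) -> GrowthStepResult:
    """Explicit-Euler biomass update x <- x + (mu - m) x dt for every agent.

    Concentrations are read from the agent's block in the solved solute
    fields.  Starved cells lose mass at the maintenance rate, floored at
    a small positive mass.  Radii are refreshed afterwards.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    lattice = fields.lattice
    b = lattice.block_size
    n = len(pop)
    mu = np.zeros(n)
    active = pop.attached | include_floating
    ix = (np.floor((pop.x % pop.width) / b).astype(int) % lattice.nx)
    iy = np.clip(np.floor(pop.y / b).astype(int), 0, lattice.ny - 1)
    consumed = {name: 0.0 for name in fields.concentrations}
    produced = {name: 0.0 for name in fields.concentrations}
    maint = np.zeros(n)
    for k, spec in enumerate(pop.species):
        sel = active & (pop.species_idx == k)
        if not sel.any():
            continue
        maint[sel] = spec.maintenance
        for sub, (mumax, ks) in spec.kinetics.items():
            s_local = fields.concentrations[sub][ix[sel], iy[sel]]
            mu_sub = monod_mu(s_local, mumax, ks)
            mu[sel] += mu_sub
            eaten = float(np.sum(mu_sub * pop.mass[sel]) / spec.yield_xs
                          * biomass_to_substrate * dt)
            consumed[sub] += eaten
            if sub in spec.productions:
                prod_name, fp = spec.productions[sub]
                produced[prod_name] += fp * eaten
    delta = (mu - maint) * pop.mass * dt
    delta[~active] = 0.0
    mu[~active] = 0.0
    new_mass = pop.mass + delta
    floored = new_mass < MASS_FLOOR
    new_mass[floored] = MASS_FLOOR
    delta = new_mass - pop.mass
    pop.mass = new_mass
    pop.update_radii()
    pop.invalidate_index()
    return GrowthStepResult(mu_total=mu, delta_mass=delta,
                            consumed=consumed, produced=produced)


def divide(pop, rng: np.random.Generator,
           lattice: SubstratumLattice | None = None,
           split_cv: float = 0.0) -> int:
    """Split every agent whose mass reached its division threshold.

    Parent keeps its position; the daughter center is placed at contact
    distance (sum of the post-split radii) in a uniformly random
    direction, truncated at the first solid contact when a lattice is
    given.  Both cells draw fresh division thresholds.  Total mass is
    conserved exactly.  Returns the number of divisions.
    """
    ready = np.flatnonzero(pop.mass >= pop.division_threshold)
    if ready.size == 0:
        return 0
    frac = np.full(ready.size, 0.5)
    if split_cv > 0:
        frac = np.clip(truncated_normal(0.5, split_cv, ready.size, rng),
                       0.05, 0.95)
    m_parent = pop.mass[ready] * frac
    m_daughter = pop.mass[ready] - m_parent
    pop.mass[ready] = m_parent
    pop.division_threshold[ready] = draw_division_thresholds(ready.size, rng)
    pop.update_radii()
    from .agents import radius_from_mass

    r_d = radius_from_mass(m_daughter, r1=pop.r1, scaling=pop.radius_scaling)
    ang = rng.uniform(0.0, 2 * np.pi, size=ready.size)
    dist = pop.radius[ready] + r_d
    dx, dy = np.cos(ang) * dist, np.sin(ang) * dist
    xs, ys = pop.x[ready] + dx, pop.y[ready] + dy
    if lattice is not None:
        for k in range(ready.size):
            p = ready[k]
            xs[k], ys[k] = mechanics.wall_constrain(
                (pop.x[p], pop.y[p]), (xs[k], ys[k]), r_d[k], lattice)
    ys = np.clip(ys, 0.0, pop.height)
    thresholds = draw_division_thresholds(ready.size, rng)
    pop.add(pop.species_idx[ready], xs, ys, m_daughter,
            attached=pop.attached[ready], division_threshold=thresholds)
    return int(ready.size)
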