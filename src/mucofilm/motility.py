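"""Planktonic run-and-tumble phase: initial attachment and invasions.

Unattached bacteria move in straight 1-second runs (10 um/s) separated
by random reorientations whose mean absolute turn is 45 degrees.  A cell
whose path touches the substratum surface or an already-attached cell
stops at the first point of contact and becomes a permanent biofilm
member (attachment is absorbing; detachment is not modeled).  Cells
still planktonic when the phase ends are kept floating and frozen:
they take no further part in growth, mechanics, or analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import mechanics
from .agents import Population
from .scenario_config import ScenarioConfig, SubstratumLattice


@dataclass(frozen=True)
class PlanktonicPhase:
    """Timing and release-band geometry of one planktonic episode."""

    duration: float = 100.0       # s
    count: int = 200
    band_lo: float = 0.0          # um, lower edge of the release band
    band_hi: float = 0.0          # um, upper edge


def release_band(config: ScenarioConfig, lattice: SubstratumLattice,
                 biofilm_top: float | None = None) -> tuple[float, float]:
    """Release band for seeding planktonic cells.

    Initial attachment: from ``release_offset`` (default 200 um) above
    the pillar tops up to just below the top boundary; on short domains
    the offset is clamped so a band always exists.  Invasions
    (``biofilm_top`` given) release in a band starting just above the
    current biofilm surface and extending ``release_offset`` upward.
    """
    top = config.geometry.height
    margin = 2.0
    if biofilm_top is not None:
        lo = max(biofilm_top, config.geometry.pillar_top) + margin
        hi = min(lo + config.release_offset, top - margin)
    else:
        floor = config.geometry.pillar_top
        lo = floor + config.release_offset
        if lo >= top - margin:  # clamped band on scaled-down domains
            lo = floor + 0.5 * (top - floor)
        hi = top - margin
    if lo >= hi:
        raise ValueError("release band is empty: no fluid space above the biofilm")
    return lo, hi


def turn_angle(rng: np.random.Generator, size=None, mean_deg: float = 45.0,
               distribution: str = "normal"):
    """Signed turn angles (radians) with E|turn| = ``mean_deg`` degrees.

    ``normal``: Normal(0, sigma) with sigma = mean * sqrt(pi/2);
    ``exponential``: exponential magnitude with a random sign.
    """
    mean = np.deg2rad(mean_deg)
    if distribution == "normal":
        return rng.normal(0.0, mean * np.sqrt(np.pi / 2), size=size)
    if distribution == "exponential":
        mag = rng.exponential(mean, size=size)
        return mag * rng.choice([-1.0, 1.0], size=size)
    raise ValueError(f"unknown turn-angle distribution {distribution!r}")


def seed_planktonic(pop: Population, config: ScenarioConfig,
                    counts: dict[str, int], band: tuple[float, float],
                    rng: np.random.Generator) -> np.ndarray:
    """Place unattached cells uniformly at random inside the release band.

    Species are interleaved deterministically for the ``alternating``
    placement pattern and shuffled for ``random``; counts are exact
    either way.  Returns the new agent ids.
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError("empty release band")
    sp_index = {sp.name: i for i, sp in enumerate(pop.species)}
    order: list[int] = []
    remaining = {name: c for name, c in counts.items() if c > 0}
    names = sorted(remaining, key=lambda n: sp_index[n])
    while remaining:
        for name in list(names):
            if remaining.get(name, 0) > 0:
                order.append(sp_index[name])
                remaining[name] -= 1
                if remaining[name] == 0:
                    del remaining[name]
    order_arr = np.array(order, dtype=np.int32)
    n = order_arr.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if config.placement_pattern == "random":
        rng.shuffle(order_arr)
    x = rng.uniform(0.0, pop.width, size=n)
    y = rng.uniform(lo, hi, size=n)
    from .metabolism import draw_division_thresholds, draw_initial_masses

    masses = draw_initial_masses(n, rng)
    thresholds = draw_division_thresholds(n, rng)
    heading = rng.uniform(0.0, 2 * np.pi, size=n)
    return pop.add(order_arr, x, y, masses, attached=False,
                   division_threshold=thresholds, heading=heading)


def _agent_contact_t(pop: Population, start, disp, radius: float,
                     exclude_id: int) -> float:
    """First parameter t in [0, 1] at which the moving circle touches an
    attached agent, or inf."""
    if pop.n_attached == 0:
        return np.inf
    att = np.flatnonzero(pop.attached)
    ytop = float(pop.y[att].max() + pop.radius[att].max())
    if min(start[1], start[1] + disp[1]) - radius > ytop + 1e-9:
        return np.inf
    length = float(np.hypot(*disp))
    mid = (start[0] + 0.5 * disp[0], start[1] + 0.5 * disp[1])
    reach = 0.5 * length + radius + float(pop.radius[att].max()) + 1e-9
    dx = pop.delta_x(pop.x[att], mid[0])
    dy = pop.y[att] - mid[1]
    near = np.hypot(dx, dy) <= reach
    if not near.any():
        return np.inf
    best = np.inf
    for k in att[near]:
        # |start + t*disp - q| = radius + r_q  (minimum-image in x)
        qx = start[0] + pop.delta_x(pop.x[k], start[0])
        qy = pop.y[k]
        rsum = radius + pop.radius[k]
        fx, fy = start[0] - qx, start[1] - qy
        a = disp[0] ** 2 + disp[1] ** 2
        if a <= 0:
            continue
        b = 2 * (fx * disp[0] + fy * disp[1])
        c = fx * fx + fy * fy - rsum * rsum
        if c <= 0:  # already touching
            return 0.0
        disc = b * b - 4 * a * c
        if disc < 0:
            continue
        t = (-b - np.sqrt(disc)) / (2 * a)
        if 0.0 <= t <= 1.0:
            best = min(best, t)
    return best


def solid_top(lattice: SubstratumLattice) -> float:
    """Highest solid surface in the lattice (um), cached on the lattice."""
    cached = getattr(lattice, "_solid_top", None)
    if cached is None:
        rows = np.flatnonzero(lattice.solid.any(axis=0))
        cached = (rows.max() + 1) * lattice.block_size if rows.size else 0.0
        lattice._solid_top = cached
    return cached


def _solid_contact_t(start, disp, radius: float,
                     lattice: SubstratumLattice) -> float:
    """First t at which the swept circle touches the substratum, or inf."""
    if min(start[1], start[1] + disp[1]) - radius > solid_top(lattice) + 1e-9:
        return np.inf
    end = (start[0] + disp[0], start[1] + disp[1])
    best = np.inf
    for rect in mechanics._segment_blocks(start, end, radius + 1e-9, lattice):
        t = mechanics._first_contact_rect(start, disp, radius, rect)
        if t is not None:
            best = min(best, t)
    return best


def run_and_tumble_step(pop: Population, idx: int, dt: float,
                        rng: np.random.Generator,
                        lattice: SubstratumLattice,
                        config: ScenarioConfig) -> bool:
    """Advance one unattached agent by one motility step.

    The heading is rotated by a random turn, the cell runs speed*dt along
    it, and the swept circle is tested against the substratum and every
    attached agent; on contact the cell stops there and attaches
    permanently.  Returns True when the agent attached.
    """
    if pop.attached[idx]:
        raise ValueError("run_and_tumble_step on an attached agent")
    spec = pop.species[pop.species_idx[idx]]
    pop.heading[idx] += turn_angle(rng, mean_deg=spec.motility.mean_turn_angle,
                                   distribution=config.turn_angle_distribution)
    step = spec.motility.speed * dt
    disp = (step * np.cos(pop.heading[idx]), step * np.sin(pop.heading[idx]))
    start = (pop.x[idx], pop.y[idx])
    r = float(pop.radius[idx])
    t_solid = _solid_contact_t(start, disp, r, lattice)
    t_agent = _agent_contact_t(pop, start, disp, r, exclude_id=idx)
    t = min(t_solid, t_agent, 1.0)
    newx = (start[0] + t * disp[0]) % pop.width
    newy = start[1] + t * disp[1]
    # reflect off the top boundary instead of leaving the domain
    if newy > pop.height - r:
        newy = pop.height - r
    if newy < r:
        newy = r
    pop.x[idx] = newx
    pop.y[idx] = newy
    attached = t < 1.0 - 1e-12
    if attached:
        pop.attached[idx] = True
        pop.invalidate_index()
    return attached


def run_planktonic_phase(pop: Population, ids: np.ndarray,
                         config: ScenarioConfig, lattice: SubstratumLattice,
                         rng: np.random.Generator,
                         duration: float | None = None) -> int:
    """Run the full planktonic episode for the given cohort.

    Moves every still-unattached cohort member once per move timestep
    until the phase duration elapses; returns how many attached.
    """
    if duration is None:
        duration = config.attachment_duration
    id_to_row = {int(a): i for i, a in enumerate(pop.id)}
    rows = np.array([id_to_row[int(a)] for a in ids], dtype=int)
    dt = min((pop.species[pop.species_idx[r]].motility.move_timestep
              for r in rows), default=1.0)
    nsteps = int(round(duration / dt))
    for _ in range(nsteps):
        for r in rows:
            if not pop.attached[r]:
                run_and_tumble_step(pop, r, dt, rng, lattice, config)
        if pop.attached[rows].all():
            break
    return int(pop.attached[rows].sum())
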