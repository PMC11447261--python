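"""Deterministic synthetic fixtures: labeled point patterns and
hand-solvable reaction-diffusion columns.

These live in the package (not in the test tree) so that demo scenarios
and oracle comparisons can be run offline from the CLI as well as from
tests.  Every fixture is a pure function of its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import Population
from .scenario_config import (SoluteSpec, SpeciesSpec, SubstratumLattice,
                              BLOCK_SIZE)


def _two_species() -> list[SpeciesSpec]:
    return [SpeciesSpec(name="green"), SpeciesSpec(name="brown")]


def make_pattern(kind: str, n: int = 400, spacing: float = 1.0,
                 seed: int = 0, separation: float = 100.0) -> Population:
    """Construct a labeled point pattern as an attached Population.

    ``checkerboard``: sqrt(n) x sqrt(n) grid with species alternating in
    both directions (a torus when the side count is even).
    ``two_blobs``: two compact single-species Gaussian blobs, centers
    ``separation`` apart.  ``monolayer``: a single species-0 row.
    ``random``: uniform positions with equal random species labels.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    species = _two_species()
    if kind == "checkerboard":
        side = int(round(np.sqrt(n)))
        if side * side != n:
            raise ValueError("checkerboard needs a square n")
        width = side * spacing
        pop = Population(width, max(width, 1.0), species)
        ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
        labels = ((ii + jj) % 2).ravel().astype(np.int32)
        pop.add(labels, (ii.ravel() * spacing), (jj.ravel() * spacing),
                1.0, attached=True)
    elif kind == "two_blobs":
        half = n // 2
        width = 4 * separation
        pop = Population(width, width, species)
        sd = separation / 20
        c1, c2 = separation, 2 * separation
        x1 = rng.normal(c1, sd, half)
        y1 = rng.normal(c1, sd, half)
        x2 = rng.normal(c2 + separation, sd, n - half)
        y2 = rng.normal(c1, sd, n - half)
        pop.add(np.zeros(half, dtype=np.int32), x1, y1, 1.0, attached=True)
        pop.add(np.ones(n - half, dtype=np.int32), x2, y2, 1.0, attached=True)
    elif kind == "monolayer":
        width = n * spacing
        pop = Population(width, max(width, 10.0), species)
        pop.add(np.zeros(n, dtype=np.int32), np.arange(n) * spacing,
                np.full(n, 1.0), 1.0, attached=True)
    elif kind == "random":
        width = max(np.sqrt(n) * spacing * 2, 10.0)
        pop = Population(width, width, species)
        labels = np.arange(n, dtype=np.int32) % 2
        rng.shuffle(labels)
        pop.add(labels, rng.uniform(0, width, n), rng.uniform(0, width, n),
                1.0, attached=True)
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")
    return pop


@dataclass
class ColumnProblem:
    """1D diffusion column with a uniform zeroth-order sink.

    Top boundary Dirichlet at ``sb``, floor no-flux, sink rate ``r0``
    (concentration per hour) applied uniformly; the steady profile is
    the parabola  S(y) = Sb - (r0 / 2 D) (H^2 - y^2).
    """

    lattice: SubstratumLattice
    solute: SoluteSpec
    r0: float
    sb: float
    d: float

    @property
    def height(self) -> float:
        return self.lattice.height

    def analytic(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return self.sb - self.r0 / (2 * self.d) * (self.height ** 2 - y ** 2)

    def cell_centers(self) -> np.ndarray:
        b = self.lattice.block_size
        return (np.arange(self.lattice.ny) + 0.5) * b

    def as_transport_inputs(self):
        """Species list and biomass field that realize the uniform sink
        through the Monod machinery (Ks tiny so the sink is zeroth order
        wherever S stays positive); use biomass_to_substrate = 1."""
        from . import solute_transport as st

        species = [SpeciesSpec(name="sink",
                               kinetics={"S": (1.0, 1e-9)},
                               yield_xs=1.0, maintenance=0.0)]
        vol = st.block_volume(self.lattice)
        biomass = np.full((1, self.lattice.nx, self.lattice.ny),
                          self.r0 * vol)
        return species, biomass


def make_column_problem(height_blocks: int, sink_rate: float,
                        sb: float = 4.0, d: float = 1.0e4,
                        block_size: float = BLOCK_SIZE) -> ColumnProblem:
    """Single-column FVM fixture with its closed-form parabolic solution.

    Raises when the sink is strong enough to drive the analytic profile
    negative (the fixture would be invalid: concentrations cannot be
    negative).
    """
    if height_blocks < 3:
        raise ValueError("need at least 3 blocks")
    height = height_blocks * block_size
    if sink_rate < 0:
        raise ValueError("sink rate must be >= 0")
    s_floor = sb - sink_rate / (2 * d) * height ** 2
    if s_floor < 0:
        raise ValueError("sink too strong: analytic profile goes negative")
    nx = 1
    solid = np.zeros((nx, height_blocks), dtype=bool)
    # no solid base here: the floor itself is the no-flux boundary
    lattice = SubstratumLattice.__new__(SubstratumLattice)
    lattice.nx = nx
    lattice.ny = height_blocks
    lattice.block_size = block_size
    lattice.solid = solid
    solute = SoluteSpec(name="S", d_bulk=d, biofilm_d_factor=1.0,
                        top_concentration=sb)
    return ColumnProblem(lattice=lattice, solute=solute, r0=sink_rate,
                         sb=sb, d=d)


def solve_column(problem: ColumnProblem) -> np.ndarray:
    """Independent discrete oracle for the column fixture: a directly
    assembled 1D tridiagonal system (length ny array of cell values)."""
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    lat = problem.lattice

    ny = lat.ny
    h = lat.block_size
    d = problem.d
    main = np.zeros(ny)
    lower = np.zeros(ny - 1)
    upper = np.zeros(ny - 1)
    rhs = np.full(ny, problem.r0)
    for i in range(ny):
        if i > 0:
            main[i] -= d / h ** 2
            lower[i - 1] = d / h ** 2
        if i < ny - 1:
            main[i] -= d / h ** 2
            upper[i] = d / h ** 2
        else:
            main[i] -= 2 * d / h ** 2
            rhs[i] -= 2 * d / h ** 2 * problem.sb
    a = sp.diags([lower, main, upper], [-1, 0, 1], format="csc")
    return spla.spsolve(a, rhs)
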