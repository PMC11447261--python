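"""Pseudo-steady-state reaction-diffusion solve on the block lattice.

Each growth timestep, every solute field S satisfies

    div(D(X) grad S) + R(S) = 0

on the non-solid blocks, with fixed concentrations on the top boundary
(the bulk fluid), no-flux on solid faces and the domain floor, and
periodic vertical side walls.  R lumps Monod consumption and by-product
generation of the agents resident in each block; its dependence on S is
handled by Picard (lagged-coefficient) iteration, with the Monod
denominator frozen at the previous iterate so each linear system stays
an M-matrix and the solution stays non-negative.

A five-point finite-volume stencil with harmonic-mean face diffusivities
is used; diffusivity is D_bulk in fluid blocks and 0.8 D_bulk inside
biofilm blocks (blocks holding at least one attached agent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .scenario_config import SoluteSpec, SpeciesSpec, SubstratumLattice

FLUID, BIOFILM, SOLID = 0, 1, 2

#: block volume for mass <-> concentration conversion (10 x 10 x 1 um^3 with
#: the 1 um depth of field)
def block_volume(lattice: SubstratumLattice) -> float:
    return lattice.block_size ** 2 * 1.0


class TransportError(RuntimeError):
    """Linear-solve failure or Picard non-convergence."""


def classify_blocks(pop, lattice: SubstratumLattice) -> np.ndarray:
    """Per-block {FLUID, BIOFILM, SOLID} classification.

    A non-solid block is biofilm when it contains at least one attached
    agent center.
    """
    codes = np.where(lattice.solid, SOLID, FLUID).astype(np.int8)
    if pop is not None and len(pop):
        att = pop.attached
        ix = (np.floor((pop.x[att] % pop.width) / lattice.block_size)
              .astype(int) % lattice.nx)
        iy = np.floor(pop.y[att] / lattice.block_size).astype(int)
        iy = np.clip(iy, 0, lattice.ny - 1)
        occ = np.zeros((lattice.nx, lattice.ny), dtype=bool)
        occ[ix, iy] = True
        codes[occ & ~lattice.solid] = BIOFILM
    return codes


def biomass_by_block(pop, lattice: SubstratumLattice) -> np.ndarray:
    """Summed attached-agent mass per (species, block); shape (n_sp, nx, ny)."""
    n_sp = len(pop.species)
    out = np.zeros((n_sp, lattice.nx, lattice.ny))
    att = pop.attached
    if not att.any():
        return out
    ix = (np.floor((pop.x[att] % pop.width) / lattice.block_size)
          .astype(int) % lattice.nx)
    iy = np.clip(np.floor(pop.y[att] / lattice.block_size).astype(int),
                 0, lattice.ny - 1)
    np.add.at(out, (pop.species_idx[att], ix, iy), pop.mass[att])
    return out


@dataclass
class ReactionAssembly:
    """Per-block reaction rates (concentration units per hour) per solute."""

    consumption: dict[str, np.ndarray]
    production: dict[str, np.ndarray]

    def net(self, name: str) -> np.ndarray:
        return self.production[name] - self.consumption[name]


def assemble_reactions(biomass: np.ndarray, concentrations: dict[str, np.ndarray],
                       species: list[SpeciesSpec], lattice: SubstratumLattice,
                       biomass_to_substrate: float) -> ReactionAssembly:
    """Monod reaction rates per block at the given concentrations.

    Consumption of solute i: sum over species k of
    (1/Y) mu_max(k,i) S_i/(S_i+Ks(i,k)) X_k / V_block; production adds
    f_p times the consumption of the precursor substrate.  ``biomass``
    is the (n_species, nx, ny) attached-mass field.
    """
    if np.any(biomass < 0):
        raise ValueError("negative biomass")
    vol = block_volume(lattice)
    names = list(concentrations)
    consumption = {n: np.zeros((lattice.nx, lattice.ny)) for n in names}
    production = {n: np.zeros((lattice.nx, lattice.ny)) for n in names}
    for k, spec in enumerate(species):
        xk = biomass[k] * biomass_to_substrate / vol  # concentration units
        if not np.any(xk):
            continue
        for sub, (mumax, ks) in spec.kinetics.items():
            s = concentrations[sub]
            rate = (mumax / spec.yield_xs) * s / (s + ks) * xk
            consumption[sub] += rate
            if sub in spec.productions:
                prod_name, fp = spec.productions[sub]
                production[prod_name] += fp * rate
    return ReactionAssembly(consumption=consumption, production=production)


@dataclass
class SoluteField:
    """Solved concentration fields plus the pieces needed for audits."""

    lattice: SubstratumLattice
    solutes: list[SoluteSpec]
    concentrations: dict[str, np.ndarray]
    codes: np.ndarray
    diffusivity: dict[str, np.ndarray]
    picard_iterations: int = 0
    residual: float = 0.0
    clipped: int = 0
    host_mask: np.ndarray | None = None

    def top_influx(self, name: str) -> float:
        """Net diffusive influx across the top boundary, conc x um^3 / h."""
        lat = self.lattice
        h = lat.block_size
        spec = next(s for s in self.solutes if s.name == name)
        s_top = self.concentrations[name][:, -1]
        d_top = self.diffusivity[name][:, -1]
        nonsolid = self.codes[:, -1] != SOLID
        flux = 2 * d_top[nonsolid] / h * (spec.top_concentration - s_top[nonsolid])
        return float(np.sum(flux) * h * 1.0)


def _host_adjacent(lattice: SubstratumLattice) -> np.ndarray:
    """Non-solid blocks sharing a face with a solid block."""
    s = lattice.solid
    adj = np.zeros_like(s)
    adj |= np.roll(s, 1, axis=0) | np.roll(s, -1, axis=0)
    adj[:, :-1] |= s[:, 1:]
    adj[:, 1:] |= s[:, :-1]
    return adj & ~s


def solve_steady_state(lattice: SubstratumLattice, solutes: list[SoluteSpec],
                       species: list[SpeciesSpec], biomass: np.ndarray,
                       pop=None, codes: np.ndarray | None = None,
                       initial: dict[str, np.ndarray] | None = None,
                       biomass_to_substrate: float = 1.0,
                       rtol: float = 1e-6, max_picard: int = 100,
                       ) -> SoluteField:
    """Solve every solute field to pseudo-steady state.

    ``biomass`` is the (n_species, nx, ny) attached-mass field (see
    :func:`biomass_by_block`); ``codes`` may be supplied to avoid
    reclassification.  ``initial`` seeds the Picard iteration.
    """
    nx, ny = lattice.nx, lattice.ny
    h = lattice.block_size
    if codes is None:
        codes = classify_blocks(pop, lattice)
    nonsolid = codes != SOLID
    idx = -np.ones((nx, ny), dtype=int)
    cells = np.argwhere(nonsolid)
    idx[cells[:, 0], cells[:, 1]] = np.arange(cells.shape[0])
    n = cells.shape[0]
    host_mask = _host_adjacent(lattice)

    diffusivity = {}
    base = {}
    for spec in solutes:
        d = np.where(codes == BIOFILM, spec.biofilm_d_factor * spec.d_bulk,
                     spec.d_bulk)
        d[~nonsolid] = 0.0
        diffusivity[spec.name] = d
        base[spec.name] = _laplacian(lattice, d, nonsolid, idx, cells, spec,
                                     host_mask)

    conc = {}
    for spec in solutes:
        if initial is not None and spec.name in initial:
            conc[spec.name] = initial[spec.name].copy()
        else:
            conc[spec.name] = np.full((nx, ny), spec.top_concentration)
        conc[spec.name][~nonsolid] = 0.0

    vol = block_volume(lattice)
    clipped = 0
    residual = np.inf
    it = 0
    for it in range(1, max_picard + 1):
        residual = 0.0
        new_conc = {}
        for spec in solutes:
            name = spec.name
            a, rhs0, dirichlet = base[name]
            # lagged Monod: consumption = [sum_k C_k/(S_old+Ks_k)] * S
            sink = np.zeros((nx, ny))
            source = np.zeros((nx, ny))
            for k, sp_k in enumerate(species):
                xk = biomass[k] * biomass_to_substrate / vol
                if not np.any(xk):
                    continue
                if name in sp_k.kinetics:
                    mumax, ks = sp_k.kinetics[name]
                    sink += (mumax / sp_k.yield_xs) * xk / (conc[name] + ks)
                for sub, (prod_name, fp) in sp_k.productions.items():
                    if prod_name == name:
                        mumax, ks = sp_k.kinetics[sub]
                        sj = conc[sub]
                        source += fp * (mumax / sp_k.yield_xs) * sj / (sj + ks) * xk
            amat = a + sp.diags(np.where(dirichlet, 0.0, sink[nonsolid]))
            rhs = rhs0 + np.where(dirichlet, 0.0, source[nonsolid])
            try:
                sol = spla.spsolve(amat.tocsr(), rhs)
            except Exception as exc:  # pragma: no cover
                raise TransportError(f"linear solve failed for {name}: {exc}")
            if not np.all(np.isfinite(sol)):
                raise TransportError(f"non-finite solution for {name}")
            neg = sol < 0
            if neg.any():
                clipped += int(neg.sum())
                sol = np.clip(sol, 0.0, None)
            field_new = np.zeros((nx, ny))
            field_new[cells[:, 0], cells[:, 1]] = sol
            scale = max(float(np.max(np.abs(sol))), 1e-12)
            residual = max(residual,
                           float(np.max(np.abs(field_new - conc[name]))) / scale)
            new_conc[name] = field_new
        conc = new_conc
        if residual < rtol:
            break
    if residual >= rtol:
        raise TransportError(
            f"Picard iteration did not converge: residual {residual:.3e} "
            f"after {it} iterations")
    return SoluteField(lattice=lattice, solutes=list(solutes),
                       concentrations=conc, codes=codes,
                       diffusivity=diffusivity, picard_iterations=it,
                       residual=residual, clipped=clipped, host_mask=host_mask)


def _laplacian(lattice: SubstratumLattice, d: np.ndarray, nonsolid: np.ndarray,
               idx: np.ndarray, cells: np.ndarray, spec: SoluteSpec,
               host_mask: np.ndarray):
    """Sparse negative-Laplacian (sink-positive) operator, rhs, and the
    Dirichlet row mask for one solute.

    Rows are scaled per unit volume so reaction terms add directly.
    Host-source solutes get identity rows (S = host concentration) on
    blocks face-adjacent to solid.
    """
    nx, ny = lattice.nx, lattice.ny
    h = lattice.block_size
    n = cells.shape[0]
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    host = (spec.host_source_concentration is not None)
    dirichlet = np.zeros(n, dtype=bool)
    if host:
        dirichlet = host_mask[cells[:, 0], cells[:, 1]]
    diag = np.zeros(n)
    for p in range(n):
        ix, iy = cells[p]
        if dirichlet[p]:
            rows.append(p); cols.append(p); vals.append(1.0)
            rhs[p] = spec.host_source_concentration
            continue
        dp = d[ix, iy]
        for ox, oy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            jx, jy = (ix + ox) % nx, iy + oy
            if jy >= ny:
                # top boundary: Dirichlet at the face, half-cell spacing
                coef = 2 * dp / h ** 2
                diag[p] += coef
                rhs[p] += coef * spec.top_concentration
                continue
            if jy < 0 or not nonsolid[jx, jy]:
                continue  # no-flux at floor and solid faces
            dq = d[jx, jy]
            dface = 2 * dp * dq / (dp + dq) if dp + dq > 0 else 0.0
            coef = dface / h ** 2
            diag[p] += coef
            rows.append(p); cols.append(idx[jx, jy]); vals.append(-coef)
    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(np.where(dirichlet, 0.0, diag))
    a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return a.tocsr(), rhs, dirichlet
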