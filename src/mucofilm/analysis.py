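"""Population and structure metrics for labeled point patterns.

The segregation index of a species is the fraction of same-species
agents among the k = 8 Euclidean nearest neighbors of each agent,
averaged over the species.  Values near 1 indicate clustered,
segregated patches; low values indicate intermixing.  The multispecies
generalization is a row-normalized matrix M whose entry (i, j) is the
fraction of type-j agents among the neighbors of type-i agents, so its
diagonal recovers the per-species index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class SegregationResult:
    species_names: list[str]
    per_agent: np.ndarray        # same-type neighbor fraction per agent
    agent_species: np.ndarray    # species index per agent row
    per_species: dict[str, float]
    matrix: np.ndarray           # row-normalized neighbor-type fractions
    k: int = 8


def knn_indices(x: np.ndarray, y: np.ndarray, k: int, width: float,
                height: float, ids: np.ndarray | None = None) -> np.ndarray:
    """k nearest neighbors of each point (self excluded), periodic in x.

    Distance ties at the k-th neighbor are broken by agent id so the
    result is deterministic.
    """
    n = x.size
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points for k={k} neighbors")
    if ids is None:
        ids = np.arange(n)
    ybox = max(2 * height, float(np.max(y)) * 2 + 1.0)
    tree = cKDTree(np.column_stack([x % width, y]), leafsize=2,
                   boxsize=[width, ybox])
    # query a couple of extra neighbors so ties at rank k can be re-sorted
    kq = min(n, k + 3)
    dist, idx = tree.query(np.column_stack([x % width, y]), k=kq)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        cand = [(round(dist[i, j], 9), ids[idx[i, j]], idx[i, j])
                for j in range(kq) if idx[i, j] != i]
        cand.sort()
        out[i] = [c[2] for c in cand[:k]]
    return out


def segregation_index(pop=None, k: int = 8, *, x=None, y=None,
                      species_idx=None, species_names=None,
                      width: float | None = None, height: float | None = None,
                      attached_only: bool = True) -> SegregationResult:
    """Per-species mean same-type KNN fraction and the full neighbor matrix.

    Accepts either a Population (default: attached agents only) or raw
    arrays.  Requires at least k+1 agents.
    """
    if pop is not None:
        mask = pop.attached if attached_only else np.ones(len(pop), dtype=bool)
        x = pop.x[mask]
        y = pop.y[mask]
        species_idx = pop.species_idx[mask]
        ids = pop.id[mask]
        species_names = [sp.name for sp in pop.species]
        width = pop.width
        height = pop.height
    else:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        species_idx = np.asarray(species_idx, dtype=int)
        ids = np.arange(x.size)
        if species_names is None:
            species_names = [str(i) for i in range(int(species_idx.max()) + 1)]
    n_sp = len(species_names)
    nbr = knn_indices(x, y, k, width, height, ids=ids)
    nbr_species = species_idx[nbr]                       # (n, k)
    same = nbr_species == species_idx[:, None]
    per_agent = same.mean(axis=1)
    counts = np.zeros((n_sp, n_sp))
    for i in range(n_sp):
        sel = species_idx == i
        if sel.any():
            counts[i] = np.bincount(nbr_species[sel].ravel(), minlength=n_sp)
    rows = counts.sum(axis=1, keepdims=True)
    matrix = np.divide(counts, rows, out=np.zeros_like(counts), where=rows > 0)
    per_species = {species_names[i]: float(per_agent[species_idx == i].mean())
                   for i in range(n_sp) if (species_idx == i).any()}
    return SegregationResult(species_names=list(species_names),
                             per_agent=per_agent, agent_species=species_idx,
                             per_species=per_species, matrix=matrix, k=k)


def relative_abundance(pop, basis: str = "biomass",
                       attached_only: bool = True) -> dict[str, float]:
    """Per-species fraction of total attached biomass (or cell count)."""
    mask = pop.attached if attached_only else np.ones(len(pop), dtype=bool)
    if not mask.any():
        raise ValueError("no attached agents")
    if basis == "biomass":
        weights = pop.mass[mask]
    elif basis == "count":
        weights = np.ones(int(mask.sum()))
    else:
        raise ValueError(f"unknown abundance basis {basis!r}")
    total = float(weights.sum())
    out = {}
    for i, sp in enumerate(pop.species):
        sel = pop.species_idx[mask] == i
        out[sp.name] = float(weights[sel].sum()) / total
    return out
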