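"""Agent data model and population container.

Agents are circular bacteria with continuous positions in a 2D box that
is periodic in x.  The population is stored struct-of-arrays so that the
mechanics, transport and analysis steps can operate on whole NumPy
vectors; :class:`Bacterium` is a lightweight per-agent view used in
tests and small-scale code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .scenario_config import SpeciesSpec


def radius_from_mass(mass, species=None, *, r1: float = 0.5,
                     scaling: str = "area"):
    """Cell radius (um) from cell mass.

    The default ``area`` rule keeps areal density constant in the 2D
    plane (r = r1 * sqrt(m)); ``volume`` uses the 3D cube-root rule.
    ``r1`` is the radius at unit mass.
    """
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be positive")
    if scaling == "area":
        r = r1 * np.sqrt(mass)
    elif scaling == "volume":
        r = r1 * np.cbrt(mass)
    else:
        raise ValueError(f"unknown radius scaling {scaling!r}")
    return float(r) if r.ndim == 0 else r


@dataclass
class Bacterium:
    """Single-agent view; mirrors one row of the population arrays."""

    id: int
    species: SpeciesSpec
    x: float
    y: float
    mass: float
    radius: float
    attached: bool
    division_threshold: float


class Population:
    """Struct-of-arrays container for all agents in a simulation.

    x is wrapped into [0, width); the KD-tree spatial index treats x as
    periodic with period ``width`` and y as effectively non-periodic.
    """

    def __init__(self, width: float, height: float, species: list[SpeciesSpec],
                 r1: float = 0.5, radius_scaling: str = "area"):
        self.width = float(width)
        self.height = float(height)
        self.species = list(species)
        self.r1 = r1
        self.radius_scaling = radius_scaling
        self._next_id = 0
        n0 = 0
        self.id = np.empty(n0, dtype=np.int64)
        self.species_idx = np.empty(n0, dtype=np.int32)
        self.x = np.empty(n0)
        self.y = np.empty(n0)
        self.mass = np.empty(n0)
        self.radius = np.empty(n0)
        self.attached = np.empty(n0, dtype=bool)
        self.division_threshold = np.empty(n0)
        self.heading = np.empty(n0)  # radians; meaningful while planktonic
        self._tree: cKDTree | None = None
        self._tree_ids: np.ndarray | None = None
        self._tree_attached_only: bool | None = None

    # -- basic bookkeeping -------------------------------------------------

    def __len__(self) -> int:
        return self.id.size

    @property
    def n_attached(self) -> int:
        return int(np.count_nonzero(self.attached))

    def add(self, species_idx, x, y, mass, attached=False,
            division_threshold=2.0, heading=0.0) -> np.ndarray:
        """Append agents (scalars or equal-length arrays); returns new ids."""
        x = np.atleast_1d(np.asarray(x, dtype=float)) % self.width
        n = x.size
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.id = np.concatenate([self.id, ids])
        self.species_idx = np.concatenate(
            [self.species_idx, np.broadcast_to(np.asarray(species_idx, dtype=np.int32), (n,))])
        self.x = np.concatenate([self.x, x])
        self.y = np.concatenate([self.y, np.broadcast_to(np.asarray(y, dtype=float), (n,))])
        mass = np.broadcast_to(np.asarray(mass, dtype=float), (n,))
        self.mass = np.concatenate([self.mass, mass])
        self.radius = np.concatenate(
            [self.radius, radius_from_mass(mass, r1=self.r1, scaling=self.radius_scaling)])
        self.attached = np.concatenate(
            [self.attached, np.broadcast_to(np.asarray(attached, dtype=bool), (n,))])
        self.division_threshold = np.concatenate(
            [self.division_threshold,
             np.broadcast_to(np.asarray(division_threshold, dtype=float), (n,))])
        self.heading = np.concatenate(
            [self.heading, np.broadcast_to(np.asarray(heading, dtype=float), (n,))])
        self.invalidate_index()
        return ids

    def update_radii(self) -> None:
        self.radius = radius_from_mass(self.mass, r1=self.r1,
                                       scaling=self.radius_scaling)

    def agent(self, idx: int) -> Bacterium:
        return Bacterium(
            id=int(self.id[idx]),
            species=self.species[self.species_idx[idx]],
            x=float(self.x[idx]), y=float(self.y[idx]),
            mass=float(self.mass[idx]), radius=float(self.radius[idx]),
            attached=bool(self.attached[idx]),
            division_threshold=float(self.division_threshold[idx]))

    # -- periodic metric ---------------------------------------------------

    def delta_x(self, x1, x2):
        """Signed minimum-image x-separation x1 - x2."""
        d = np.asarray(x1) - np.asarray(x2)
        return (d + self.width / 2) % self.width - self.width / 2

    def distance(self, p1, p2):
        """Periodic-x Euclidean distance between points (x, y)."""
        dx = self.delta_x(p1[0], p2[0])
        dy = np.asarray(p1[1]) - np.asarray(p2[1])
        return np.hypot(dx, dy)

    # -- spatial index -----------------------------------------------------

    def invalidate_index(self) -> None:
        self._tree = None
        self._tree_attached_only = None

    def build_index(self, attached_only: bool = True) -> cKDTree:
        """(Re)build the periodic KD-tree over agent centers.

        y is embedded in a box twice the domain height so that the tree's
        periodic wrap never produces a shorter image in y for queries with
        radius below the domain height.
        """
        mask = self.attached if attached_only else np.ones(len(self), dtype=bool)
        pts = np.column_stack([self.x[mask] % self.width, self.y[mask]])
        ybox = max(2 * self.height, 1.0)
        self._tree = cKDTree(pts, leafsize=2, boxsize=[self.width, ybox])
        self._tree_ids = np.flatnonzero(mask)
        self._tree_attached_only = attached_only
        return self._tree

    def neighbors_within(self, center, r: float,
                         attached_only: bool = True) -> np.ndarray:
        """Agent ids whose centers lie within distance r of ``center``."""
        if self._tree is None or self._tree_attached_only != attached_only:
            self.build_index(attached_only=attached_only)
        idx = self._tree.query_ball_point([center[0] % self.width, center[1]], r)
        rows = (self._tree_ids[np.asarray(idx, dtype=int)] if len(idx)
                else np.empty(0, dtype=int))
        return np.sort(self.id[rows])

    # -- export ------------------------------------------------------------

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "id": self.id,
            "species": [self.species[i].name for i in self.species_idx],
            "x": self.x, "y": self.y,
            "mass": self.mass, "radius": self.radius,
            "attached": self.attached,
        })
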