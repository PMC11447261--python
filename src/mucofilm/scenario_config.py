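"""Scenario definitions: geometry, species, solutes, interaction presets.

Everything a simulation needs is collected in a :class:`ScenarioConfig`;
the named presets reproduce the dual-species interaction scenarios
(competition, neutralism, commensalism, mutualism), the newcomer-invasion
variants and the five-species communities on the crypt-like substratum.

Units
-----
Lengths are in micrometres, times in hours unless a field says otherwise.
Concentrations live in one consistent arbitrary family in which the bulk
nutrient boundary value is 4.0 and the Monod half-saturation constant is
0.2.  Cell mass is carried in units of the mean initial cell mass (1.0);
``biomass_to_substrate`` converts one unit of cell mass into
concentration x volume units when biomass appears in a mass balance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

BLOCK_SIZE = 10.0  # um, lattice resolution of the substratum / FVM grid

#: default kinetic parameters shared by every baseline scenario
MU_MAX = 0.3          # 1/h
KS = 0.2              # concentration units
YIELD_XS = 0.15       # biomass per substrate, dimensionless
MAINTENANCE = 0.03    # 1/h
SB = 4.0              # bulk nutrient concentration at the top boundary
D_BULK = 2.1e6        # um^2/h, small-molecule diffusivity in water
BIOFILM_D_FACTOR = 0.8
#: substrate-unit x um^3 carried by one unit of cell mass (glucose-equivalent
#: anchoring of the arbitrary concentration family, calibrated so mature
#: biofilms reach the 50-200 um thickness regime within 120 h while growth
#: stays strongly diffusion-limited; see docs/methods.md)
BIOMASS_TO_SUBSTRATE = 3.0e3
#: by-product mass produced per unit substrate consumed (1 - Y_x/S)
PRODUCTION_FRACTION = 0.85


class ConfigurationError(ValueError):
    """Raised when a scenario description is internally inconsistent."""


@dataclass(frozen=True)
class CryptGeometry:
    """Corrugated crypt-like substratum made of rectangular pillars.

    The defaults are the crypt topography used throughout the baseline
    scenarios: 80 um tall, 20 um wide pillars spaced 30 um apart on a
    one-block-thick solid base.
    """

    width: float = 500.0
    height: float = 500.0
    pillar_height: float = 80.0
    pillar_diameter: float = 20.0
    pillar_spacing: float = 30.0
    base_thickness: float = BLOCK_SIZE

    def __post_init__(self) -> None:
        for name in ("width", "height", "pillar_height", "pillar_diameter",
                     "pillar_spacing", "base_thickness"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
            if abs(v / BLOCK_SIZE - round(v / BLOCK_SIZE)) > 1e-9:
                raise ConfigurationError(
                    f"{name}={v} is not a multiple of the {BLOCK_SIZE} um block size")
        if self.pillar_height > 0 and self.pillar_diameter <= 0:
            raise ConfigurationError("pillars need a positive diameter")

    @property
    def pillar_top(self) -> float:
        """Height (um) of the pillar tops above the domain floor."""
        return self.base_thickness + self.pillar_height


@dataclass
class SubstratumLattice:
    """Boolean solid mask of the substratum on the block lattice.

    ``solid[ix, iy]`` is True where block column ``ix`` / row ``iy``
    (y increasing away from the host) is solid.  The mask tiles
    periodically in x.
    """

    nx: int
    ny: int
    block_size: float
    solid: np.ndarray  # bool, shape (nx, ny)

    def __post_init__(self) -> None:
        self.solid = np.asarray(self.solid, dtype=bool)
        if self.solid.shape != (self.nx, self.ny):
            raise ConfigurationError("solid mask shape does not match (nx, ny)")
        if self.ny and not self.solid[:, 0].all():
            raise ConfigurationError("bottom lattice row must be entirely solid")
        # no floating solids: every solid block is anchored to the bottom
        below = np.ones(self.nx, dtype=bool)
        for iy in range(self.ny):
            col = self.solid[:, iy]
            if np.any(col & ~below):
                raise ConfigurationError("solid mask contains floating blocks")
            below = col

    @property
    def width(self) -> float:
        return self.nx * self.block_size

    @property
    def height(self) -> float:
        return self.ny * self.block_size

    def is_solid_at(self, x: float, y: float) -> bool:
        """Solid test for a point, periodic in x; outside y -> False."""
        ix = int(np.floor((x % self.width) / self.block_size))
        iy = int(np.floor(y / self.block_size))
        if iy < 0 or iy >= self.ny:
            return False
        return bool(self.solid[ix, iy])


def build_crypt_lattice(geometry: CryptGeometry) -> SubstratumLattice:
    """Discretize the pillared crypt topography onto the block lattice.

    Pillars are rectangular at block resolution, regularly spaced with
    period ``diameter + spacing`` starting at x = 0, on a solid base of
    ``base_thickness``.  ``pillar_height == 0`` yields the flat-surface
    control geometry.
    """
    b = BLOCK_SIZE
    nx = int(round(geometry.width / b))
    ny = int(round(geometry.height / b))
    solid = np.zeros((nx, ny), dtype=bool)
    nbase = int(round(geometry.base_thickness / b))
    solid[:, :nbase] = True
    if geometry.pillar_height > 0:
        ndiam = int(round(geometry.pillar_diameter / b))
        nspace = int(round(geometry.pillar_spacing / b))
        nh = int(round(geometry.pillar_height / b))
        period = ndiam + nspace
        if period <= 0:
            raise ConfigurationError("pillar period must be positive")
        for ix in range(nx):
            if ix % period < ndiam:
                solid[ix, nbase:nbase + nh] = True
    return SubstratumLattice(nx=nx, ny=ny, block_size=b, solid=solid)


@dataclass(frozen=True)
class SoluteSpec:
    """One diffusing chemical species (bulk nutrient or metabolic by-product).

    ``top_concentration`` is the Dirichlet value at the top boundary (the
    bulk fluid): Sb for bulk nutrients, 0 for by-products that wash out.
    ``host_source_concentration``, when set, pins the concentration on
    fluid blocks face-adjacent to the solid substratum (host secretion).
    """

    name: str
    d_bulk: float = D_BULK
    biofilm_d_factor: float = BIOFILM_D_FACTOR
    top_concentration: float = 0.0
    host_source_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.d_bulk <= 0:
            raise ConfigurationError("d_bulk must be positive")
        if not 0 < self.biofilm_d_factor <= 1:
            raise ConfigurationError("biofilm_d_factor must be in (0, 1]")
        if self.top_concentration < 0:
            raise ConfigurationError("top_concentration must be >= 0")
        if (self.host_source_concentration is not None
                and self.host_source_concentration < 0):
            raise ConfigurationError("host_source_concentration must be >= 0")


@dataclass(frozen=True)
class Motility:
    """Run-and-tumble parameters for the planktonic phase."""

    speed: float = 10.0          # um/s
    mean_turn_angle: float = 45.0  # deg, mean |turn| per step
    move_timestep: float = 1.0   # s


@dataclass(frozen=True)
class SpeciesSpec:
    """Per-species kinetics and metabolic wiring.

    ``kinetics`` maps a consumed solute name to its (mu_max, Ks) Monod
    pair; growth on multiple substrates is additive.  ``productions``
    maps a consumed substrate to the by-product it generates, with a
    production fraction f_p of the consumed substrate mass.
    """

    name: str
    kinetics: dict[str, tuple[float, float]] = field(default_factory=dict)
    productions: dict[str, tuple[str, float]] = field(default_factory=dict)
    yield_xs: float = YIELD_XS
    maintenance: float = MAINTENANCE
    motility: Motility = field(default_factory=Motility)

    def __post_init__(self) -> None:
        for sub, (mu, ks) in self.kinetics.items():
            if mu < 0:
                raise ConfigurationError(f"mu_max for {sub} must be >= 0")
            if ks <= 0:
                raise ConfigurationError(f"Ks for {sub} must be > 0")
        if not 0 < self.yield_xs <= 1:
            raise ConfigurationError("yield must be in (0, 1]")
        if self.maintenance < 0:
            raise ConfigurationError("maintenance must be >= 0")
        for sub, (_, fp) in self.productions.items():
            if sub not in self.kinetics:
                raise ConfigurationError(
                    f"production from {sub} without consuming it")
            if not 0 <= fp <= 1:
                raise ConfigurationError("production fraction must be in [0, 1]")


@dataclass(frozen=True)
class InvasionEvent:
    """Scheduled arrival of planktonic newcomers during biofilm growth."""

    time: float            # h
    species: str
    count: int = 100
    duration: float = 100.0  # s of planktonic run-and-tumble


@dataclass
class ScenarioConfig:
    """Full description of one simulation run."""

    geometry: CryptGeometry = field(default_factory=CryptGeometry)
    solutes: list[SoluteSpec] = field(default_factory=list)
    species: list[SpeciesSpec] = field(default_factory=list)
    initial_counts: dict[str, int] = field(default_factory=dict)
    placement_pattern: str = "random"        # random | alternating
    growth_timestep: float = 0.25            # h, <= 15 min
    attachment_duration: float = 100.0       # s
    release_offset: float = 200.0            # um above pillar tops
    end_time: float = 120.0                  # h
    max_attached: int | None = None          # optional early cutoff
    thickness_cap: float | None = 200.0      # um
    invasions: list[InvasionEvent] = field(default_factory=list)
    seed: int = 0
    output_cadence: float = 1.0              # h between snapshots
    biomass_to_substrate: float = BIOMASS_TO_SUBSTRATE
    radius_unit_mass: float = 0.5            # um at unit mass
    radius_scaling: str = "area"             # area | volume
    shove_tol: float = 1e-2                  # um residual overlap
    shove_max_iters: int = 50
    division_split_cv: float = 0.0           # 0 -> exact 50/50 split
    turn_angle_distribution: str = "normal"  # normal | exponential

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.growth_timestep <= 0 or self.growth_timestep > 0.25 + 1e-12:
            raise ConfigurationError("growth timestep must be in (0, 0.25] h")
        if self.end_time < 0:
            raise ConfigurationError("end time must be >= 0")
        if self.placement_pattern not in ("random", "alternating"):
            raise ConfigurationError(f"unknown pattern {self.placement_pattern}")
        names = {s.name for s in self.species}
        if len(names) != len(self.species):
            raise ConfigurationError("duplicate species names")
        solute_names = {s.name for s in self.solutes}
        for sp in self.species:
            for sub in sp.kinetics:
                if sub not in solute_names:
                    raise ConfigurationError(
                        f"species {sp.name} consumes unknown solute {sub}")
            for sub, (prod, _) in sp.productions.items():
                if prod not in solute_names:
                    raise ConfigurationError(
                        f"species {sp.name} produces unknown solute {prod}")
        for name in self.initial_counts:
            if name not in names:
                raise ConfigurationError(f"initial count for unknown species {name}")
        for ev in self.invasions:
            if ev.species not in names:
                raise ConfigurationError(f"invasion of unknown species {ev.species}")

    @property
    def total_initial(self) -> int:
        return sum(self.initial_counts.values())

    def species_index(self) -> dict[str, int]:
        return {sp.name: i for i, sp in enumerate(self.species)}


# ---------------------------------------------------------------------------
# interaction-network presets


def _bulk(name: str) -> SoluteSpec:
    return SoluteSpec(name=name, top_concentration=SB)


def _byproduct(name: str) -> SoluteSpec:
    return SoluteSpec(name=name, top_concentration=0.0)


_SPECIES_NAMES = ("green", "brown", "red", "blue", "purple")


def make_interaction_preset(kind: str, n_species: int = 2,
                            *, byproduct_only_recipient: bool = False,
                            f_p: float = PRODUCTION_FRACTION,
                            ) -> tuple[list[SoluteSpec], list[SpeciesSpec]]:
    """Build the solute and species lists for a named interaction type.

    ``competition``: every species consumes the single shared bulk
    nutrient A.  ``neutralism``: each species consumes its own bulk
    nutrient.  ``commensalism``: species i consumes its bulk nutrient
    and feeds by-product C_i to species i+1 (the recipient also keeps
    its own bulk nutrient unless ``byproduct_only_recipient``).
    ``mutualism``: a ring of bidirectional cross-feeders, each consuming
    its own bulk nutrient plus the by-product of its partner; for two
    species this is the classic A->C / B->D exchange.
    """
    if n_species < 2:
        raise ConfigurationError("interaction presets need >= 2 species")
    if n_species > len(_SPECIES_NAMES):
        raise ConfigurationError(f"at most {len(_SPECIES_NAMES)} species supported")
    names = _SPECIES_NAMES[:n_species]
    kin = (MU_MAX, KS)
    solutes: list[SoluteSpec]
    species: list[SpeciesSpec]

    if kind == "competition":
        solutes = [_bulk("A")]
        species = [SpeciesSpec(name=n, kinetics={"A": kin}) for n in names]
    elif kind == "neutralism":
        solutes = [_bulk(chr(ord("A") + i)) for i in range(n_species)]
        species = [SpeciesSpec(name=n, kinetics={solutes[i].name: kin})
                   for i, n in enumerate(names)]
    elif kind == "commensalism":
        bulk = [chr(ord("A") + i) for i in range(n_species)]
        prod = [f"C{i + 1}" for i in range(n_species - 1)]
        solutes = [_bulk(b) for b in bulk] + [_byproduct(p) for p in prod]
        species = []
        for i, n in enumerate(names):
            kinetics: dict[str, tuple[float, float]] = {}
            productions: dict[str, tuple[str, float]] = {}
            if i == 0 or not byproduct_only_recipient:
                kinetics[bulk[i]] = kin
            if i > 0:
                kinetics[prod[i - 1]] = kin
            if i < n_species - 1:
                productions[bulk[i]] = (prod[i], f_p)
            species.append(SpeciesSpec(name=n, kinetics=kinetics,
                                       productions=productions))
        if byproduct_only_recipient:
            solutes = [s for s in solutes
                       if any(s.name in sp.kinetics or
                              any(p == s.name for p, _ in sp.productions.values())
                              for sp in species)]
    elif kind == "mutualism":
        bulk = [chr(ord("A") + i) for i in range(n_species)]
        prod = [f"P{i + 1}" for i in range(n_species)]  # P_i made by species i
        solutes = [_bulk(b) for b in bulk] + [_byproduct(p) for p in prod]
        species = []
        for i, n in enumerate(names):
            partner = (i - 1) % n_species  # consume the by-product of the ring partner
            species.append(SpeciesSpec(
                name=n,
                kinetics={bulk[i]: kin, prod[partner]: kin},
                productions={bulk[i]: (prod[i], f_p)},
            ))
    else:
        raise ConfigurationError(f"unknown interaction kind: {kind}")
    return solutes, species


def _baseline(kind: str, n_species: int = 2, **kwargs) -> ScenarioConfig:
    solutes, species = make_interaction_preset(kind, n_species)
    counts = {sp.name: 200 // n_species for sp in species}
    return ScenarioConfig(solutes=solutes, species=species,
                          initial_counts=counts, **kwargs)


def _invasion(kind: str, **kwargs) -> ScenarioConfig:
    """Two-species resident community, competing newcomer at t = 25 h.

    The invader (red) enters a pairwise competitive relationship over a
    bulk nutrient: it consumes the first resident's bulk solute A with
    baseline kinetics (in the competition scenario A is already shared
    by everyone).
    """
    solutes, species = make_interaction_preset(kind, 2)
    kin = (MU_MAX, KS)
    invader = SpeciesSpec(name="red", kinetics={"A": kin})
    counts = {sp.name: 100 for sp in species}
    counts["red"] = 0
    return ScenarioConfig(
        solutes=solutes, species=species + [invader], initial_counts=counts,
        invasions=[InvasionEvent(time=25.0, species="red", count=100)],
        **kwargs)


def _five_species(flavor: str, **kwargs) -> ScenarioConfig:
    """Five-species communities mirroring the polymicrobial scenarios."""
    kin = (MU_MAX, KS)
    if flavor == "crossfeeding":
        # three-species mutualistic ring plus two commensal recipients
        solutes, species = make_interaction_preset("mutualism", 3)
        extra = [_byproduct("P4"), _byproduct("P5")]
        solutes = solutes + extra
        commensals = [
            SpeciesSpec(name="blue", kinetics={"P1": kin},
                        productions={"P1": ("P4", PRODUCTION_FRACTION)}),
            SpeciesSpec(name="purple", kinetics={"P2": kin, "P4": kin}),
        ]
        species = species + commensals
    elif flavor == "mixed":
        # one cross-feeding pair, one (slower) competitive pair, one neutral
        solutes, species = make_interaction_preset("mutualism", 2)
        solutes = solutes + [_bulk("E"), _bulk("F")]
        slow = (0.25 * MU_MAX, KS)
        species = species + [
            SpeciesSpec(name="red", kinetics={"E": slow}),
            SpeciesSpec(name="blue", kinetics={"E": slow}),
            SpeciesSpec(name="purple", kinetics={"F": kin}),
        ]
    elif flavor == "competition":
        solutes, species = make_interaction_preset("competition", 5)
    else:
        raise ConfigurationError(f"unknown five-species flavor {flavor}")
    counts = {sp.name: 40 for sp in species}
    return ScenarioConfig(solutes=solutes, species=species,
                          initial_counts=counts, **kwargs)


_PRESETS = {
    "competition2": lambda **kw: _baseline("competition", 2, **kw),
    "neutralism2": lambda **kw: _baseline("neutralism", 2, **kw),
    "commensalism2": lambda **kw: _baseline("commensalism", 2, **kw),
    "mutualism2": lambda **kw: _baseline("mutualism", 2, **kw),
    "invasion_competition": lambda **kw: _invasion("competition", **kw),
    "invasion_neutralism": lambda **kw: _invasion("neutralism", **kw),
    "invasion_commensalism": lambda **kw: _invasion("commensalism", **kw),
    "invasion_mutualism": lambda **kw: _invasion("mutualism", **kw),
    "crossfeeding5": lambda **kw: _five_species("crossfeeding", **kw),
    "mixed5": lambda **kw: _five_species("mixed", **kw),
    "competition5": lambda **kw: _five_species("competition", **kw),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str, **overrides) -> ScenarioConfig:
    """Instantiate a named scenario preset; overrides are ScenarioConfig fields."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}")
    return _PRESETS[name](**overrides)


# ---------------------------------------------------------------------------
# YAML (de)serialization


def to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    d["geometry"] = CryptGeometry(**d.get("geometry", {}))
    d["solutes"] = [SoluteSpec(**s) for s in d.get("solutes", [])]
    species = []
    for s in d.get("species", []):
        s = dict(s)
        s["kinetics"] = {k: tuple(v) for k, v in s.get("kinetics", {}).items()}
        s["productions"] = {k: tuple(v) for k, v in s.get("productions", {}).items()}
        if "motility" in s and isinstance(s["motility"], dict):
            s["motility"] = Motility(**s["motility"])
        species.append(SpeciesSpec(**s))
    d["species"] = species
    d["invasions"] = [InvasionEvent(**e) for e in d.get("invasions", [])]
    return ScenarioConfig(**d)


def load_scenario(path) -> ScenarioConfig:
    """Load a scenario from a YAML file; a top-level ``preset`` key selects a
    named preset and the remaining keys override its fields."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "preset" in d:
        name = d.pop("preset")
        base = to_dict(preset(name))
        base.update(d)
        d = base
    return from_dict(d)


def save_scenario(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=False)
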