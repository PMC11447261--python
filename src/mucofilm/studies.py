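"""Reproducible scenario studies at configurable scale.

The baseline dual-species interaction scenarios, the growth-rate
asymmetry variants and the newcomer-invasion experiments, wrapped so
that tests, scripts, and users run the same conditions and only choose
the problem size (domain, agent cutoff, horizon) and seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np

from . import engine
from .scenario_config import (CryptGeometry, ScenarioConfig, SpeciesSpec,
                              preset)

INTERACTIONS = ("competition", "neutralism", "commensalism", "mutualism")


@dataclass(frozen=True)
class StudyScale:
    """Problem size for a scenario study.

    The default is the reduced domain used for quantitative readouts:
    a 250 um wide, 250 um tall crypt field run to 72 h or until 5000
    attached agents exist, whichever comes first.
    """

    width: float = 250.0
    height: float = 250.0
    end_time: float = 72.0
    max_attached: int | None = 5000
    total_cells: int = 200


def scale_mu(species: SpeciesSpec, factor: float) -> SpeciesSpec:
    """Species with every mu_max multiplied by ``factor``."""
    kin = {sub: (mu * factor, ks) for sub, (mu, ks) in species.kinetics.items()}
    return dataclasses.replace(species, kinetics=kin)


def study_config(kind: str, scale: StudyScale = StudyScale(), *,
                 abundance: float = 0.5, mu_factor_brown: float = 1.0,
                 invasion: bool = False, seed: int = 0) -> ScenarioConfig:
    """Build one study scenario.

    ``abundance`` is the initial fraction of the brown species;
    ``mu_factor_brown`` scales the brown species' growth rates (the
    asymmetric-kinetics studies use 0.25); ``invasion`` selects the
    three-species variant with a competing newcomer at t = 25 h.
    """
    name = (f"invasion_{kind}" if invasion else f"{kind}2")
    cfg = preset(name,
                 geometry=CryptGeometry(width=scale.width, height=scale.height),
                 end_time=scale.end_time, max_attached=scale.max_attached,
                 seed=seed)
    n_brown = int(round(scale.total_cells * abundance))
    counts = {"green": scale.total_cells - n_brown, "brown": n_brown}
    if invasion:
        counts["red"] = 0
        cfg.invasions = [replace(ev, count=scale.total_cells // 2)
                         for ev in cfg.invasions]
    cfg.initial_counts = counts
    if mu_factor_brown != 1.0:
        cfg.species = [scale_mu(sp, mu_factor_brown) if sp.name == "brown"
                       else sp for sp in cfg.species]
    cfg.validate()
    return cfg


def run_study(cfg: ScenarioConfig, seed: int) -> engine.SimulationResult:
    return engine.run(cfg, seed=seed)


def segregation_study(kind: str, seeds, scale: StudyScale = StudyScale(),
                      **kwargs) -> dict:
    """Seed-averaged per-species segregation indices for one interaction."""
    per_species: dict[str, list[float]] = {}
    results = []
    for seed in seeds:
        res = run_study(study_config(kind, scale, seed=seed, **kwargs), seed)
        seg = res.segregation()
        for name, value in seg.per_species.items():
            per_species.setdefault(name, []).append(value)
        results.append(res)
    means = {name: float(np.mean(v)) for name, v in per_species.items()}
    means["both"] = float(np.mean([means[n] for n in ("green", "brown")
                                   if n in means]))
    return {"mean": means, "per_seed": per_species, "results": results}


def abundance_study(kind: str, seeds, scale: StudyScale = StudyScale(),
                    abundance: float = 0.5, **kwargs) -> dict:
    """Initial and seed-averaged final brown abundance (biomass basis)."""
    initials, finals = [], []
    for seed in seeds:
        res = run_study(study_config(kind, scale, abundance=abundance,
                                     seed=seed, **kwargs), seed)
        ts = res.timeseries
        initials.append(float(ts["abundance_brown"].iloc[0]))
        finals.append(float(ts["abundance_brown"].iloc[-1]))
    return {"initial": float(np.mean(initials)),
            "final": float(np.mean(finals)),
            "finals": finals,
            "series_final": finals}


def asymmetry_study(kind: str, seeds, scale: StudyScale = StudyScale(),
                    mu_factor_brown: float = 0.25) -> dict:
    """Growth-rate asymmetry: brown grows at ``mu_factor_brown`` of green."""
    finals = []
    trajectories = []
    for seed in seeds:
        res = run_study(study_config(kind, scale, seed=seed,
                                     mu_factor_brown=mu_factor_brown), seed)
        ts = res.timeseries
        finals.append(float(ts["abundance_brown"].iloc[-1]))
        trajectories.append(ts["abundance_brown"].to_numpy())
    return {"final": float(np.mean(finals)), "finals": finals,
            "trajectories": trajectories}


def invasion_study(kind: str, seeds, scale: StudyScale = StudyScale()) -> dict:
    """Competing newcomer at t = 25 h: seed-averaged final red abundance."""
    finals = []
    for seed in seeds:
        res = run_study(study_config(kind, scale, invasion=True, seed=seed),
                        seed)
        finals.append(res.final_abundance().get("red", 0.0))
    return {"final": float(np.mean(finals)), "finals": finals}
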