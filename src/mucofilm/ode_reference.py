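"""Well-mixed ODE comparison model.

The community is reduced to total biomass per species and one
concentration per solute inside a fixed biofilm volume, fed from the
bulk across a diffusional boundary layer with mass-transfer coefficient
K = D A / L.  Kinetics, yields, and by-product production fractions are
identical to the agent-based model; all spatial structure is discarded,
which is precisely the contrast the comparison is designed to expose.

    dx_k/dt = (sum_i mu_max S_i/(S_i + Ks(i,k)) - m) x_k
    dS_i/dt = K/V (Sb_i - S_i) - consumption_i + production_i
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .scenario_config import (D_BULK, ScenarioConfig, SoluteSpec, SpeciesSpec,
                              BIOMASS_TO_SUBSTRATE)


@dataclass
class ODEModel:
    """Well-mixed model sharing species/solute definitions with the ABM.

    ``x0`` holds total biomass per species in cell-mass units;
    concentrations are in the same family as the ABM (bulk nutrient 4.0).
    Geometry defaults: cross-section A = 500 x 1 um^2, diffusion length
    L = 400 um, biofilm height L' = 200 um.
    """

    species: list[SpeciesSpec]
    solutes: list[SoluteSpec]
    x0: np.ndarray
    area: float = 500.0          # um^2 (500 um wide x 1 um deep)
    diffusion_length: float = 400.0
    biofilm_height: float = 200.0
    d: float = D_BULK
    biomass_to_substrate: float = BIOMASS_TO_SUBSTRATE

    @property
    def v_biofilm(self) -> float:
        return self.area * self.biofilm_height

    @property
    def k_transfer(self) -> float:
        return self.d * self.area / self.diffusion_length

    @classmethod
    def from_scenario(cls, config: ScenarioConfig, **kwargs) -> "ODEModel":
        """Initial biomass = the mass of the configured initial cells."""
        x0 = np.array([float(config.initial_counts.get(sp.name, 0))
                       for sp in config.species])
        return cls(species=list(config.species), solutes=list(config.solutes),
                   x0=x0, biomass_to_substrate=config.biomass_to_substrate,
                   **kwargs)


def ode_rhs(t: float, state: np.ndarray, model: ODEModel) -> np.ndarray:
    """Right-hand side over state [x_1..x_m, S_1..S_l]."""
    m = len(model.species)
    x = np.maximum(state[:m], 0.0)
    s = np.maximum(state[m:], 0.0)
    s_idx = {sp.name: i for i, sp in enumerate(model.solutes)}
    v = model.v_biofilm
    kv = model.k_transfer / v
    dx = np.zeros(m)
    ds = np.array([kv * (spec.top_concentration - s[i])
                   for i, spec in enumerate(model.solutes)])
    for k, spec in enumerate(model.species):
        mu_tot = 0.0
        xconc = x[k] * model.biomass_to_substrate / v
        for sub, (mumax, ks) in spec.kinetics.items():
            i = s_idx[sub]
            mu_i = mumax * s[i] / (s[i] + ks)
            mu_tot += mu_i
            uptake = mu_i * xconc / spec.yield_xs
            ds[i] -= uptake
            if sub in spec.productions:
                prod_name, fp = spec.productions[sub]
                ds[s_idx[prod_name]] += fp * uptake
        dx[k] = (mu_tot - spec.maintenance) * x[k]
    return np.concatenate([dx, ds])


@dataclass
class ODETrajectory:
    model: ODEModel
    frame: pd.DataFrame

    def final_abundance(self) -> dict[str, float]:
        last = self.frame.iloc[-1]
        cols = [f"x_{sp.name}" for sp in self.model.species]
        total = float(sum(last[c] for c in cols))
        return {sp.name: float(last[f"x_{sp.name}"]) / total
                for sp in self.model.species}


def ode_run(model: ODEModel, t_end: float,
            events: list[tuple[float, str, float]] | None = None,
            s0: np.ndarray | None = None, n_points: int = 241,
            rtol: float = 1e-8, atol: float = 1e-10) -> ODETrajectory:
    """Integrate the model, applying discrete biomass injections.

    ``events`` are (time, species name, injected mass) triples, e.g. a
    newcomer arriving at t = 25 h with the mass of 100 cells.  Solutes
    start at their bulk boundary values unless ``s0`` is given.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    m = len(model.species)
    if s0 is None:
        s0 = np.array([spec.top_concentration for spec in model.solutes])
    state = np.concatenate([model.x0.astype(float), np.asarray(s0, dtype=float)])
    breaks = [0.0]
    events = sorted(events or [])
    for t_ev, _, _ in events:
        if 0.0 < t_ev < t_end:
            breaks.append(t_ev)
    breaks.append(t_end)
    times = np.linspace(0.0, t_end, n_points)
    rows_t: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    name_to_k = {sp.name: k for k, sp in enumerate(model.species)}
    for a, b in zip(breaks[:-1], breaks[1:]):
        t_eval = times[(times >= a) & (times <= b)]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        if t_eval[-1] < b:
            t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(ode_rhs, (a, b), state, args=(model,), method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        rows_t.append(sol.t)
        rows_y.append(sol.y.T)
        state = sol.y[:, -1].copy()
        for t_ev, name, mass in events:
            if abs(t_ev - b) < 1e-12:
                state[name_to_k[name]] += mass
    t_all = np.concatenate(rows_t)
    y_all = np.maximum(np.vstack(rows_y), 0.0)
    cols = ([f"x_{sp.name}" for sp in model.species]
            + [f"S_{sp.name}" for sp in model.solutes])
    frame = pd.DataFrame(y_all, columns=cols)
    frame.insert(0, "time", t_all)
    frame = frame.drop_duplicates(subset="time", keep="last").reset_index(drop=True)
    return ODETrajectory(model=model, frame=frame)
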