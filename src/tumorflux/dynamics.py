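"""Dynamic model of tumor xenograft growth in a perfused microenvironment.

The tumor is a perfectly mixed, continuously perfused compartment: a capillary
blood volume ``V_blood`` (a CSTR fed at flow ``F`` with inlet composition
``C0``) bathing a growing cell population ``X``.  The state is governed by the
five-block system

    dC/dt       = S_c r X / V_blood + (C0 F_in - C F_out) / V_blood - mu_blood C
    dm/dt       = S_m r - (eps_m + m) mu
    dX/dt       = mu X - k_d (1 - rho^n) / (k_ratio^n + rho^n) X,   rho = NAD/NADH
    dV_blood/dt = mu_blood V_blood
    dV_tumor/dt = dX/dt + dV_blood/dt

where the last equation is made dimensionally explicit through the single-cell
volume constant ``v_cell`` (cells are counted in units of 1e6 cells; 1e6 cells
of 1e-6 mm^3 each occupy 1 mm^3).  The death term is gated on the NAD+/NADH
redox ratio and is kept in its raw form: it vanishes at rho = 1 and is *negative*
(pro-growth) when rho > 1, which is the Warburg regime.

Therapeutic drugs are blood species carried by the inlet flow: a dosing
schedule switches their inlet concentration from zero to the arm's exposure at
the treatment start day, and the kinetic layer reads drug concentrations from
the blood state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import DRUG_IDS, KineticModel, load_default_parameters

__all__ = [
    "TumorState",
    "PerfusionConfig",
    "GrowthLaw",
    "DeathLaw",
    "DosingSchedule",
    "SimulationConfig",
    "Trajectory",
    "SimulationError",
    "death_rate",
    "volume_of_cells",
    "derivatives",
    "simulate",
    "default_perfusion",
    "default_growth",
    "default_death",
    "default_initial_state",
    "MM3_PER_ML",
]

MM3_PER_ML = 1000.0


class SimulationError(RuntimeError):
    """Integrator failure or non-physical state; carries the last valid time."""

    def __init__(self, message: str, last_time_day: float | None = None):
        super().__init__(message)
        self.last_time_day = last_time_day


@dataclass
class TumorState:
    """Full dynamical state.

    C: blood concentrations (mM, network blood order); m: intracellular
    concentrations (mM, network cell order); X: tumor cells (1e6 cells);
    V_blood: capillary volume (mL); V_tumor: total tumor volume (mm^3).
    """

    C: np.ndarray
    m: np.ndarray
    X: float
    V_blood: float
    V_tumor: float

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.C, self.m, [self.X, self.V_blood, self.V_tumor]]
        )

    @classmethod
    def unpack(cls, y: np.ndarray, n_blood: int, n_cell: int) -> "TumorState":
        return cls(
            C=y[:n_blood],
            m=y[n_blood : n_blood + n_cell],
            X=float(y[-3]),
            V_blood=float(y[-2]),
            V_tumor=float(y[-1]),
        )


@dataclass
class PerfusionConfig:
    """Capillary perfusion: inlet/outlet blood flows (mL/h), inlet
    composition C0 (mM, blood order), capillary growth rate (1/h)."""

    F_in: float
    F_out: float
    C0: np.ndarray
    mu_blood: float = 0.0

    def __post_init__(self) -> None:
        if self.F_in < 0 or self.F_out < 0:
            raise ValueError("flow rates must be >= 0")
        if self.mu_blood < 0:
            raise ValueError("mu_blood must be >= 0")
        self.C0 = np.asarray(self.C0, dtype=float)
        if np.any(self.C0 < 0):
            raise ValueError("C0 must be non-negative")


@dataclass
class GrowthLaw:
    """Specific growth rate law.

    mode "constant": mu = mu_max.  mode "flux": mu = mu_max * r[Vgrowth]/r_ref,
    tying growth to the instantaneous biomass-synthesis flux (r_ref defaults
    to the biomass flux at the initial state).  eps_m is the fraction of each
    intracellular pool incorporated into cell matter (mM-equivalent).
    """

    mu_max: float
    mode: str = "flux"
    r_ref: float | None = None
    eps_m: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        if self.mu_max < 0:
            raise ValueError("mu_max must be >= 0")
        if self.mode not in ("constant", "flux"):
            raise ValueError(f"unknown growth mode {self.mode!r}")


@dataclass
class DeathLaw:
    """Redox-gated Hill death law: k_d (1-rho^n)/(k_ratio^n + rho^n)."""

    k_d: float
    n: float = 2.0
    k_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.k_d < 0 or self.n <= 0 or self.k_ratio <= 0:
            raise ValueError("require k_d >= 0, n > 0, k_ratio > 0")


@dataclass
class DosingSchedule:
    """Constant drug exposures (mM in the inlet blood) from a start day on."""

    start_day: float = 12.0
    doses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for drug, dose in self.doses.items():
            if dose < 0:
                raise ValueError(f"negative dose for {drug}")


@dataclass
class SimulationConfig:
    rtol: float = 1e-6
    atol: float = 1e-9
    method: str = "LSODA"
    points_per_day: int = 4
    v_cell_mm3: float = 1e-6  # single-cell volume; 1e6 cells = 1 mm^3
    neg_tol: float = 1e-6     # tolerated undershoot (mM) before erroring


def death_rate(nad: float, nadh: float, law: DeathLaw) -> float:
    """Specific death rate (1/h) at the given NAD+/NADH concentrations."""
    if nadh <= 0:
        raise ValueError("NADH must be > 0 (NAD/NADH ratio undefined)")
    rho = nad / nadh
    return law.k_d * (1.0 - rho**law.n) / (law.k_ratio**law.n + rho**law.n)


def volume_of_cells(X: float, v_cell_mm3: float = 1e-6) -> float:
    """Volume (mm^3) of X (in 1e6 cells): X * v_cell * 1e6."""
    if np.any(np.asarray(X) < 0):
        raise ValueError("X must be >= 0")
    return X * v_cell_mm3 * 1e6


def _mu(growth: GrowthLaw, r_growth: float) -> float:
    if growth.mode == "constant":
        return growth.mu_max
    r_ref = growth.r_ref
    if r_ref is None or r_ref <= 0:
        raise ValueError("flux growth mode requires a positive r_ref")
    return growth.mu_max * max(r_growth, 0.0) / r_ref


def derivatives(
    state: TumorState,
    model: KineticModel,
    perf: PerfusionConfig,
    growth: GrowthLaw,
    death: DeathLaw,
    doses: dict[str, float] | None = None,
    config: SimulationConfig | None = None,
) -> np.ndarray:
    """Right-hand side of the five-block system, packed in state order."""
    if state.V_blood <= 0:
        raise ValueError("V_blood must be > 0")
    config = config or SimulationConfig()
    net = model.network
    C = np.maximum(state.C, 0.0)
    m = np.maximum(state.m, 0.0)
    if doses is None:
        bidx = {s: i for i, s in enumerate(net.blood_ids)}
        doses = {d: float(C[bidx[d]]) for d in DRUG_IDS if d in bidx}
    r = model.fluxes(np.concatenate([C, m]), doses)

    dC = (
        net.S_c @ r * state.X / state.V_blood
        + (perf.C0 * perf.F_in - C * perf.F_out) / state.V_blood
        - perf.mu_blood * C
    )
    j_growth = net.reaction_index(net.biomass_id)
    mu = _mu(growth, r[j_growth])
    dm = net.S_m @ r - (np.asarray(growth.eps_m) + m) * mu

    cidx = {s: i for i, s in enumerate(net.cell_ids)}
    kd = death_rate(m[cidx["NAD"]], max(m[cidx["NADH"]], 1e-12), death)
    dX = mu * state.X - kd * state.X
    dVb = perf.mu_blood * state.V_blood
    # unit bridge: dX (1e6 cells/h) -> mm^3/h via v_cell; dVb (mL/h) -> mm^3/h
    dVt = dX * config.v_cell_mm3 * 1e6 + dVb * MM3_PER_ML
    return np.concatenate([dC, dm, [dX, dVb, dVt]])


@dataclass
class Trajectory:
    """Simulated time courses on the output grid (times in days)."""

    times_day: np.ndarray
    C: np.ndarray          # (nt, n_blood)
    m: np.ndarray          # (nt, n_cell)
    X: np.ndarray
    V_blood: np.ndarray    # mL
    V_tumor: np.ndarray    # mm^3
    r: np.ndarray          # (nt, n_reactions)
    model: KineticModel = field(repr=False)

    def blood(self, species: str) -> np.ndarray:
        return self.C[:, self.model.network.blood_ids.index(species)]

    def cell(self, species: str) -> np.ndarray:
        return self.m[:, self.model.network.cell_ids.index(species)]

    def flux(self, reaction_id: str) -> np.ndarray:
        return self.r[:, self.model.network.reaction_index(reaction_id)]

    @property
    def nad_ratio(self) -> np.ndarray:
        return self.cell("NAD") / np.maximum(self.cell("NADH"), 1e-12)

    def to_dataframe(self) -> pd.DataFrame:
        net = self.model.network
        data = {"time_day": self.times_day}
        for i, s in enumerate(net.blood_ids):
            data[f"C_{s}"] = self.C[:, i]
        for i, s in enumerate(net.cell_ids):
            data[f"m_{s}"] = self.m[:, i]
        data["X_1e6cells"] = self.X
        data["V_blood_mL"] = self.V_blood
        data["V_tumor_mm3"] = self.V_tumor
        for j, rid in enumerate(net.reaction_ids):
            data[f"r_{rid}"] = self.r[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def default_perfusion(
    network=None, F_in: float = 3.0, F_out: float = 3.0, mu_blood: float = 5e-4
) -> PerfusionConfig:
    """Calibrated default perfusion for the packaged LL/2 model."""
    from .network import load_default_network

    net = network if network is not None else load_default_network()
    inlet = load_default_parameters().inlet
    C0 = np.array([inlet.get(s, 0.0) for s in net.blood_ids])
    return PerfusionConfig(F_in=F_in, F_out=F_out, C0=C0, mu_blood=mu_blood)


def default_growth(mu_max: float = 1.52e-3, mode: str = "constant") -> GrowthLaw:
    return GrowthLaw(mu_max=mu_max, mode=mode)


def default_death() -> DeathLaw:
    return DeathLaw(k_d=1.50e-3, n=6.0, k_ratio=1.0)


def default_initial_state(
    network=None,
    V_tumor0_mm3: float = 154.0,
    blood_fraction: float = 0.10,
    perf: PerfusionConfig | None = None,
) -> TumorState:
    """Initial state at day 10: 154 mm^3 split into cells and capillaries."""
    from .network import load_default_network

    net = network if network is not None else load_default_network()
    params = load_default_parameters()
    if perf is None:
        perf = default_perfusion(net)
    V_blood_mL = V_tumor0_mm3 * blood_fraction / MM3_PER_ML
    X0 = V_tumor0_mm3 * (1.0 - blood_fraction)  # 1e6 cells (1 mm^3 each)
    m0 = np.array([params.init_cell.get(s, 0.0) for s in net.cell_ids])
    # C(t0) = C0 except explicit overrides (e.g. lactate already elevated by
    # the implanted tumor at the start of the observation window)
    C0 = perf.C0.copy()
    for sp, val in params.init_blood.items():
        C0[net.blood_ids.index(sp)] = val
    return TumorState(
        C=C0, m=m0, X=X0, V_blood=V_blood_mL, V_tumor=V_tumor0_mm3
    )


def simulate(
    model: KineticModel,
    perf: PerfusionConfig,
    growth: GrowthLaw,
    death: DeathLaw,
    state0: TumorState,
    schedule: DosingSchedule | None = None,
    t0_day: float = 10.0,
    t_end_day: float = 59.0,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Integrate the system from t0 to t_end (days), drugs stepping in at the
    schedule's start day through the inlet composition."""
    if t_end_day <= t0_day:
        raise ValueError("t_end_day must be > t0_day")
    config = config or SimulationConfig()
    schedule = schedule or DosingSchedule()
    net = model.network
    n_b, n_c = len(net.blood_ids), len(net.cell_ids)
    bidx = {s: i for i, s in enumerate(net.blood_ids)}

    growth = replace(growth)
    if growth.mode == "flux" and growth.r_ref is None:
        r0 = model.fluxes(
            np.concatenate([np.maximum(state0.C, 0), np.maximum(state0.m, 0)]),
            {},
        )
        growth.r_ref = float(r0[net.reaction_index(net.biomass_id)])
        if growth.r_ref <= 0:
            raise SimulationError(
                "biomass flux at the initial state is not positive; cannot "
                "normalize flux-coupled growth", t0_day
            )

    # fast path: equivalent to derivatives() with all index lookups hoisted
    S_c, S_m = net.S_c, net.S_m
    j_growth = net.reaction_index(net.biomass_id)
    cell_index = {s: i for i, s in enumerate(net.cell_ids)}
    i_nad, i_nadh = cell_index["NAD"], cell_index["NADH"]
    drug_pos = [(d, bidx[d]) for d in DRUG_IDS if d in bidx]
    eps = np.asarray(growth.eps_m)
    v_cell_factor = config.v_cell_mm3 * 1e6

    def rhs(t_h: float, y: np.ndarray, perf_phase: PerfusionConfig):
        V_blood = y[-2]
        if V_blood <= 0:
            raise SimulationError("V_blood collapsed to zero", t_h / 24.0)
        conc = np.maximum(y[: n_b + n_c], 0.0)
        C, m = conc[:n_b], conc[n_b:]
        doses = {d: C[i] for d, i in drug_pos}
        r = model.fluxes(conc, doses)
        X = y[-3]
        dC = (S_c @ r) * (X / V_blood) \
            + (perf_phase.C0 * perf_phase.F_in - C * perf_phase.F_out) / V_blood \
            - perf_phase.mu_blood * C
        mu = _mu(growth, r[j_growth])
        dm = S_m @ r - (eps + m) * mu
        kd = death_rate(m[i_nad], max(m[i_nadh], 1e-12), death)
        dX = (mu - kd) * X
        dVb = perf_phase.mu_blood * V_blood
        dVt = dX * v_cell_factor + dVb * MM3_PER_ML
        return np.concatenate([dC, dm, [dX, dVb, dVt]])

    # phase boundaries at the treatment start
    t0_h, t_end_h = t0_day * 24.0, t_end_day * 24.0
    t_treat_h = np.clip(schedule.start_day * 24.0, t0_h, t_end_h)
    dt_out = 24.0 / config.points_per_day
    t_grid = np.arange(t0_h, t_end_h + 0.5 * dt_out, dt_out)
    t_grid[-1] = min(t_grid[-1], t_end_h)

    C0_treated = perf.C0.copy()
    for drug, dose in (schedule.doses or {}).items():
        if drug not in bidx:
            raise KeyError(f"drug {drug!r} is not a blood species")
        C0_treated[bidx[drug]] = dose
    perf_on = PerfusionConfig(perf.F_in, perf.F_out, C0_treated, perf.mu_blood)

    phases = []
    if t_treat_h > t0_h:
        phases.append((t0_h, t_treat_h, perf))
    if t_end_h > t_treat_h:
        phases.append((t_treat_h, t_end_h, perf_on))

    y = state0.pack()
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for a, b, perf_phase in phases:
        grid = t_grid[(t_grid >= a - 1e-9) & (t_grid <= b + 1e-9)]
        if grid.size == 0 or grid[0] > a:
            grid = np.concatenate([[a], grid])
        if grid[-1] < b:
            grid = np.concatenate([grid, [b]])
        sol = solve_ivp(
            rhs, (a, b), y, method=config.method, t_eval=grid,
            rtol=config.rtol, atol=config.atol, args=(perf_phase,),
        )
        if not sol.success:
            last = sol.t[-1] / 24.0 if sol.t.size else a / 24.0
            raise SimulationError(
                f"integrator failed: {sol.message}", last_time_day=last
            )
        ts.append(sol.t)
        ys.append(sol.y)
        y = sol.y[:, -1]

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # deduplicate phase-boundary points
    keep = np.concatenate([[True], np.diff(t_all) > 1e-9])
    t_all, y_all = t_all[keep], y_all[:, keep]

    conc = y_all[: n_b + n_c]
    worst = conc.min()
    if worst < -config.neg_tol:
        raise SimulationError(
            f"concentration fell to {worst:.3e} mM (beyond the clipping "
            f"tolerance {config.neg_tol})", float(t_all[-1] / 24.0)
        )
    y_all[: n_b + n_c] = np.maximum(conc, 0.0)

    r_all = np.empty((t_all.size, len(net.reactions)))
    for i in range(t_all.size):
        C_i = y_all[:n_b, i]
        doses_i = {d: float(C_i[bidx[d]]) for d in DRUG_IDS if d in bidx}
        r_all[i] = model.fluxes(y_all[: n_b + n_c, i], doses_i)

    return Trajectory(
        times_day=t_all / 24.0,
        C=y_all[:n_b].T.copy(),
        m=y_all[n_b : n_b + n_c].T.copy(),
        X=y_all[-3],
        V_blood=y_all[-2],
        V_tumor=y_all[-1],
        r=r_all,
        model=model,
    )
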