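"""Weighted least-squares estimation of the sensitive parameters.

The perfusion flows F_in, F_out (mL/h) and the cell specific growth rate mu
(1/h) are the parameters the tumor-volume data constrain; they are fitted by
minimizing the chi-square objective

    sum_n sum_t ((Y_exp[n,t] - Y[n,t](p)) / sigma[n,t])^2

over bound constraints, with a derivative-free local search (Nelder-Mead)
optionally restarted from seeded jittered initial points to hedge local
minima.  A simulator is any callable mapping a parameter dict to model tumor
volumes at the data's measurement times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

__all__ = [
    "CohortSeries",
    "FitSpec",
    "FitResult",
    "objective",
    "fit",
    "profile_sensitivity",
    "SIGMA_FLOOR_MM3",
]

#: lower bound on weights: avoids division blow-up where the cohort SD -> 0
SIGMA_FLOOR_MM3 = 1.0

#: finite penalty returned when the simulator fails at a parameter point
FAILURE_PENALTY = 1e12

Simulator = Callable[[dict], np.ndarray]


@dataclass
class CohortSeries:
    """Tumor-volume observations: times (days), mean volumes and SD (mm^3)."""

    times: np.ndarray
    y_exp: np.ndarray
    sigma: np.ndarray
    arm: str = ""
    per_mouse: np.ndarray | None = None  # optional (n_mice, n_times) matrix

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y_exp = np.asarray(self.y_exp, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times.shape != self.y_exp.shape or self.times.shape != self.sigma.shape:
            raise ValueError("times, y_exp and sigma must have equal length")
        if np.any(self.y_exp < 0):
            raise ValueError("y_exp must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        return np.maximum(self.sigma, SIGMA_FLOOR_MM3)

    @classmethod
    def from_csv(cls, path, arm: str = "") -> "CohortSeries":
        """Read (time_day, volume_mm3, sigma_mm3[, mouse_id]) CSV."""
        df = pd.read_csv(path)
        if "mouse_id" in df.columns:
            wide = df.pivot_table(
                index="mouse_id", columns="time_day", values="volume_mm3"
            )
            times = wide.columns.to_numpy(dtype=float)
            per_mouse = wide.to_numpy(dtype=float)
            return cls(
                times=times,
                y_exp=per_mouse.mean(axis=0),
                sigma=per_mouse.std(axis=0, ddof=1),
                arm=arm,
                per_mouse=per_mouse,
            )
        return cls(
            times=df["time_day"].to_numpy(dtype=float),
            y_exp=df["volume_mm3"].to_numpy(dtype=float),
            sigma=df["sigma_mm3"].to_numpy(dtype=float),
            arm=arm,
        )


@dataclass
class FitSpec:
    """Free parameters with box bounds and the initial guess p0."""

    bounds: dict[str, tuple[float, float]]
    p0: dict[str, float]
    multi_start: int = 5
    jitter: float = 0.25       # relative spread of restart points
    seed: int = 0
    method: str = "trf"        # "trf" (bounded least squares) | "nelder-mead"
    xatol: float = 1e-4        # parameter tolerance in p0-relative units
    fatol: float = 1e-9
    max_evaluations: int = 400

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not np.isfinite([lo, hi]).all() or lo >= hi:
                raise ValueError(f"{name}: bounds must be finite with lo < hi")
            if name not in self.p0:
                raise ValueError(f"{name}: missing initial guess")
            if not lo <= self.p0[name] <= hi:
                raise ValueError(f"{name}: p0 outside bounds")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)


@dataclass
class FitResult:
    p_hat: dict[str, float]
    objective_value: float
    converged: bool
    n_evaluations: int
    seed: int = 0
    n_starts: int = 1
    message: str = ""

    def report(self) -> str:
        lines = ["fitted parameters:"]
        for k, v in self.p_hat.items():
            lines.append(f"  {k} = {v:.6g}")
        lines.append(f"objective = {self.objective_value:.6g}")
        lines.append(f"converged = {self.converged}")
        lines.append(f"evaluations = {self.n_evaluations}")
        lines.append(f"seed = {self.seed}; starts = {self.n_starts}")
        return "\n".join(lines)


def objective(
    p: dict[str, float],
    data: CohortSeries | Sequence[CohortSeries],
    simulator: Simulator,
) -> float:
    """Chi-square misfit of the simulated volumes against the data.

    Simulation failures yield a large finite penalty so the optimizer can
    continue exploring.
    """
    series = [data] if isinstance(data, CohortSeries) else list(data)
    total = 0.0
    for s in series:
        try:
            y_model = np.asarray(simulator_output(simulator, p, s), dtype=float)
        except Exception:
            return FAILURE_PENALTY
        if y_model.shape != s.y_exp.shape or not np.all(np.isfinite(y_model)):
            return FAILURE_PENALTY
        resid = (s.y_exp - y_model) / s.weights
        total += float(resid @ resid)
    return total


def simulator_output(simulator: Simulator, p: dict, series: CohortSeries):
    """Call the simulator; two-argument simulators receive the series too."""
    try:
        return simulator(p, series)  # type: ignore[call-arg]
    except TypeError:
        return simulator(p)


def fit(
    spec: FitSpec,
    data: CohortSeries | Sequence[CohortSeries],
    simulator: Simulator,
) -> FitResult:
    """Bound-constrained local WLS minimization with seeded multi-start."""
    names = spec.names
    series = [data] if isinstance(data, CohortSeries) else list(data)
    lo = np.array([spec.bounds[k][0] for k in names])
    hi = np.array([spec.bounds[k][1] for k in names])
    x0 = np.array([spec.p0[k] for k in names])
    # optimize in units of the initial guess so tolerances are relative and
    # dimensionless across parameters of different magnitude
    scale = np.maximum(np.abs(x0), (hi - lo) / 100.0)

    n_evals = 0
    n_obs = sum(s.y_exp.size for s in series)

    def residuals(z: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        p = dict(zip(names, z * scale))
        out = []
        for s in series:
            try:
                y = np.asarray(simulator_output(simulator, p, s), dtype=float)
            except Exception:
                y = None
            if y is None or y.shape != s.y_exp.shape \
                    or not np.all(np.isfinite(y)):
                return np.full(n_obs, np.sqrt(FAILURE_PENALTY / n_obs))
            out.append((s.y_exp - y) / s.weights)
        return np.concatenate(out)

    def f(z: np.ndarray) -> float:
        r = residuals(z)
        return float(r @ r)

    rng = np.random.default_rng(spec.seed)
    starts = [x0 / scale]
    for _ in range(max(spec.multi_start - 1, 0)):
        jit = x0 * (1.0 + spec.jitter * rng.standard_normal(len(names)))
        starts.append(np.clip(jit, lo, hi) / scale)

    best_x, best_val, best_ok, best_msg = None, np.inf, False, ""
    for z_start in starts:
        if spec.method == "trf":
            res = least_squares(
                residuals, z_start,
                bounds=(lo / scale, hi / scale),
                xtol=spec.xatol, ftol=spec.fatol, gtol=None,
                max_nfev=spec.max_evaluations, diff_step=1e-4,
            )
            val = float(2 * res.cost)
        else:
            res = minimize(
                f, z_start, method="Nelder-Mead",
                bounds=list(zip(lo / scale, hi / scale)),
                options=dict(maxfev=spec.max_evaluations, xatol=spec.xatol,
                             fatol=spec.fatol, adaptive=True),
            )
            val = float(res.fun)
        if val < best_val:
            best_x, best_val = res.x, val
            best_ok, best_msg = bool(res.success), str(res.message)

    return FitResult(
        p_hat=dict(zip(names, np.clip(best_x * scale, lo, hi))),
        objective_value=best_val,
        converged=best_ok,
        n_evaluations=n_evals,
        seed=spec.seed,
        n_starts=len(starts),
        message=best_msg,
    )


def profile_sensitivity(
    spec: FitSpec,
    data: CohortSeries | Sequence[CohortSeries],
    simulator: Simulator,
    grids: dict[str, np.ndarray],
    p_center: dict[str, float] | None = None,
) -> pd.DataFrame:
    """1-D objective profiles: vary one parameter, hold the others at p_center
    (default: spec.p0).  Documents *why* the fitted parameters are sensitive.
    """
    center = dict(p_center if p_center is not None else spec.p0)
    rows = []
    for name, grid in grids.items():
        lo, hi = spec.bounds[name]
        for val in np.asarray(grid, dtype=float):
            if not lo <= val <= hi:
                raise ValueError(f"{name}: grid point {val} outside bounds")
            p = dict(center)
            p[name] = float(val)
            rows.append(
                {"parameter": name, "value": float(val),
                 "objective": objective(p, data, simulator)}
            )
    return pd.DataFrame(rows)
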