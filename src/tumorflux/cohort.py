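"""Synthetic mouse-cohort generator.

Emulates the statistical structure of the xenograft study: groups of n = 10
mice, randomized at day 12 when tumors reach ~130 mm^3, calipered every 3-4
days to day 59; per-mouse biological heterogeneity as a lognormal multiplier
on the specific growth rate and a normal spread of initial volumes; caliper
measurement error as multiplicative lognormal noise (error scales with tumor
size).  Everything is reproducible from a single integer seed, and the
ground-truth parameters are carried in the provenance for recovery studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import GrowthLaw, default_growth, default_perfusion
from .estimation import CohortSeries
from .kinetics import KineticModel, load_default_model
from .network import load_default_network
from .scenarios import Scenario, build_scenario, simulate_arm

__all__ = ["CohortDesign", "SyntheticCohort", "generate_cohort",
           "summarize_cohort"]

#: lethal tumor burden; PBS animals reach it by the end of the study
LETHAL_VOLUME_MM3 = 4000.0


def default_measurement_days() -> np.ndarray:
    return np.arange(10.0, 59.0 + 0.1, 3.5)


@dataclass
class CohortDesign:
    """Study-design parameters for one synthetic group of mice."""

    arm: str = "pbs"
    n_mice: int = 10
    t_start_treatment: float = 12.0
    measurement_days: np.ndarray = field(default_factory=default_measurement_days)
    v0_mean: float = 154.0      # mm^3 at day 10 (randomization threshold
    v0_sd: float = 16.0         # ~130 mm^3 is reached around day 12)
    growth_cv: float = 0.10     # per-mouse lognormal CV on mu
    noise_cv: float = 0.10      # caliper measurement CV (multiplicative)
    seed: int = 0
    censor_lethal: bool = False

    def __post_init__(self) -> None:
        self.measurement_days = np.asarray(self.measurement_days, dtype=float)
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.growth_cv < 0 or self.noise_cv < 0 or self.v0_sd < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if not np.all(np.diff(self.measurement_days) > 0):
            raise ValueError("measurement days must be increasing")


@dataclass
class SyntheticCohort:
    """Per-mouse volume matrix plus summary curves and full provenance."""

    design: CohortDesign
    per_mouse: np.ndarray          # (n_mice, n_days) mm^3
    censored: np.ndarray           # boolean, same shape
    ground_truth: dict[str, float]

    @property
    def mean_curve(self) -> np.ndarray:
        return self.per_mouse.mean(axis=0)

    @property
    def sd_curve(self) -> np.ndarray:
        if self.per_mouse.shape[0] < 2:
            return self.design.noise_cv * self.mean_curve
        return self.per_mouse.std(axis=0, ddof=1)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for i in range(self.per_mouse.shape[0]):
            for j, day in enumerate(self.design.measurement_days):
                rows.append({
                    "mouse_id": i + 1,
                    "time_day": day,
                    "volume_mm3": self.per_mouse[i, j],
                    "censored": int(self.censored[i, j]),
                })
        pd.DataFrame(rows).to_csv(path, index=False)

    def write_provenance(self, path: str | Path) -> None:
        info = {
            "arm": self.design.arm,
            "n_mice": self.design.n_mice,
            "seed": self.design.seed,
            "growth_cv": self.design.growth_cv,
            "noise_cv": self.design.noise_cv,
            "v0_mean": self.design.v0_mean,
            "v0_sd": self.design.v0_sd,
            "ground_truth": self.ground_truth,
        }
        Path(path).write_text(json.dumps(info, indent=2) + "\n",
                              encoding="utf-8")


def generate_cohort(
    design: CohortDesign,
    model: KineticModel | None = None,
    growth: GrowthLaw | None = None,
) -> SyntheticCohort:
    """Simulate each mouse and apply measurement noise; seeded and exact.

    Each mouse gets mu_i = mu * lognormal(cv) and V0_i ~ N(v0_mean, v0_sd)
    truncated at 0; trajectories come from the calibrated kinetic model and
    measurements carry multiplicative lognormal caliper noise.
    """
    net = model.network if model is not None else load_default_network()
    model = model if model is not None else load_default_model(net)
    growth = growth if growth is not None else default_growth()
    scenario = build_scenario(
        design.arm,
        t0_day=float(design.measurement_days[0]),
        t_end_day=float(design.measurement_days[-1]),
        t_start_treatment=design.t_start_treatment,
    )
    rng = np.random.default_rng(design.seed)

    # lognormal with mean 1 and the requested CV
    sig_g = np.sqrt(np.log1p(design.growth_cv**2))
    sig_n = np.sqrt(np.log1p(design.noise_cv**2))

    days = design.measurement_days
    per_mouse = np.empty((design.n_mice, days.size))
    traj_cache: dict[tuple[float, float], np.ndarray] = {}
    for i in range(design.n_mice):
        mult = rng.lognormal(-0.5 * sig_g**2, sig_g) if sig_g > 0 else 1.0
        v0 = max(rng.normal(design.v0_mean, design.v0_sd), 0.0) \
            if design.v0_sd > 0 else design.v0_mean
        key = (mult, v0)
        if key not in traj_cache:
            mouse_growth = GrowthLaw(
                mu_max=growth.mu_max * mult, mode=growth.mode,
                r_ref=growth.r_ref, eps_m=growth.eps_m,
            )
            try:
                traj = simulate_arm(
                    scenario, model=model, growth=mouse_growth,
                    V_tumor0_mm3=v0,
                )
            except Exception as err:
                raise RuntimeError(
                    f"mouse {i + 1}: scenario {design.arm!r} failed: {err}"
                ) from err
            traj_cache[key] = np.interp(days, traj.times_day, traj.V_tumor)
        clean = traj_cache[key]
        if sig_n > 0:
            noise = rng.lognormal(-0.5 * sig_n**2, sig_n, size=days.size)
        else:
            noise = 1.0
        per_mouse[i] = clean * noise

    censored = np.zeros_like(per_mouse, dtype=bool)
    if design.censor_lethal:
        for i in range(design.n_mice):
            over = np.where(per_mouse[i] > LETHAL_VOLUME_MM3)[0]
            if over.size:
                j0 = over[0]
                per_mouse[i, j0:] = np.minimum(per_mouse[i, j0:],
                                               LETHAL_VOLUME_MM3)
                censored[i, j0 + 1:] = True

    truth = {"mu": growth.mu_max, "F_in": default_perfusion(net).F_in,
             "F_out": default_perfusion(net).F_out}
    return SyntheticCohort(design=design, per_mouse=per_mouse,
                           censored=censored, ground_truth=truth)


def summarize_cohort(cohort: SyntheticCohort) -> CohortSeries:
    """Mean +/- SD series with SD as the downstream WLS weights."""
    if cohort.per_mouse.shape[0] == 0:
        raise ValueError("empty cohort")
    return CohortSeries(
        times=cohort.design.measurement_days,
        y_exp=cohort.mean_curve,
        sigma=cohort.sd_curve,
        arm=cohort.design.arm,
        per_mouse=cohort.per_mouse,
    )
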