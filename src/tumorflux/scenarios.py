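"""Named treatment arms and the end-to-end analysis pipeline.

Arms mirror the in vivo study design: a PBS control, the METABLOC bi-therapy
(alpha-lipoic acid + hydroxycitrate), its combinations with low/high-dose
metformin and diclofenac, and the full combination.  Drug exposure levels are
constant blood concentrations (mM) applied in the inlet flow from the
treatment start day; "low" is one tenth of "high".  Cisplatin is an
antimitotic outside the metabolic network, so the ``cisplatin-reference`` arm
is a data-only overlay for comparisons, never simulated mechanistically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import (
    DosingSchedule,
    GrowthLaw,
    PerfusionConfig,
    SimulationConfig,
    Trajectory,
    default_death,
    default_growth,
    default_initial_state,
    default_perfusion,
    simulate,
)
from .estimation import CohortSeries, FitSpec, fit
from .kinetics import KineticModel, load_default_model
from .network import MetabolicNetwork, load_default_network, load_network
from .structural import essential_reactions, minimal_cut_sets, write_cut_set_report

__all__ = [
    "Scenario",
    "ARMS",
    "HIGH_DOSE_MM",
    "LOW_DOSE_MM",
    "build_scenario",
    "simulate_arm",
    "make_volume_simulator",
    "default_fit_spec",
    "time_to_plateau",
    "run_pipeline",
    "compare_arms",
]

HIGH_DOSE_MM = {"LA": 0.5, "HCIT": 0.5, "METF": 1.0, "DICLO": 1.0}
LOW_DOSE_MM = {k: v / 10.0 for k, v in HIGH_DOSE_MM.items()}

#: exposure tables per named arm (mM in inlet blood after treatment start)
ARMS: dict[str, dict[str, float] | None] = {
    "pbs": {},
    "cisplatin-reference": None,  # data-only overlay, not simulated
    "metabloc": {"LA": HIGH_DOSE_MM["LA"], "HCIT": HIGH_DOSE_MM["HCIT"]},
    "metabloc_met_low": {"LA": HIGH_DOSE_MM["LA"], "HCIT": HIGH_DOSE_MM["HCIT"],
                         "METF": LOW_DOSE_MM["METF"]},
    "metabloc_met_high": {"LA": HIGH_DOSE_MM["LA"], "HCIT": HIGH_DOSE_MM["HCIT"],
                          "METF": HIGH_DOSE_MM["METF"]},
    "metabloc_diclo_low": {"LA": HIGH_DOSE_MM["LA"], "HCIT": HIGH_DOSE_MM["HCIT"],
                           "DICLO": LOW_DOSE_MM["DICLO"]},
    "metabloc_diclo_high": {"LA": HIGH_DOSE_MM["LA"], "HCIT": HIGH_DOSE_MM["HCIT"],
                            "DICLO": HIGH_DOSE_MM["DICLO"]},
    "metablocs_full": dict(HIGH_DOSE_MM),
}


@dataclass
class Scenario:
    """One treatment arm: name, exposures and the simulated time window."""

    name: str
    doses: dict[str, float] = field(default_factory=dict)
    t0_day: float = 10.0
    t_end_day: float = 59.0
    t_start_treatment: float = 12.0

    def __post_init__(self) -> None:
        for drug, dose in self.doses.items():
            if dose < 0:
                raise ValueError(f"{self.name}: negative exposure for {drug}")


def build_scenario(name: str, **overrides) -> Scenario:
    if name == "custom":
        return Scenario(name="custom", **overrides)
    if name not in ARMS:
        raise KeyError(f"unknown arm {name!r}; known: {sorted(ARMS)}")
    doses = ARMS[name]
    if doses is None:
        raise ValueError(
            f"arm {name!r} is a data-only reference and cannot be simulated"
        )
    return Scenario(name=name, doses=dict(doses), **overrides)


def simulate_arm(
    scenario: Scenario,
    model: KineticModel | None = None,
    perf: PerfusionConfig | None = None,
    growth: GrowthLaw | None = None,
    death=None,
    config: SimulationConfig | None = None,
    V_tumor0_mm3: float = 154.0,
) -> Trajectory:
    """Simulate one arm with the calibrated defaults (overridable)."""
    net = model.network if model is not None else load_default_network()
    model = model if model is not None else load_default_model(net)
    perf = perf if perf is not None else default_perfusion(net)
    growth = growth if growth is not None else default_growth()
    death = death if death is not None else default_death()
    state0 = default_initial_state(net, V_tumor0_mm3=V_tumor0_mm3, perf=perf)
    schedule = DosingSchedule(scenario.t_start_treatment, scenario.doses)
    return simulate(
        model, perf, growth, death, state0, schedule,
        scenario.t0_day, scenario.t_end_day, config,
    )


def make_volume_simulator(
    arm: str = "pbs",
    model: KineticModel | None = None,
    config: SimulationConfig | None = None,
    V_tumor0_mm3: float = 154.0,
):
    """Simulator for the estimation layer: p -> volumes at the data times.

    ``p`` may contain F_in, F_out (mL/h) and mu (1/h); unlisted parameters
    keep their calibrated defaults.
    """
    net = model.network if model is not None else load_default_network()
    model = model if model is not None else load_default_model(net)
    scenario = build_scenario(arm)
    base_perf = default_perfusion(net)
    base_growth = default_growth()

    def simulator(p: dict, series: CohortSeries) -> np.ndarray:
        perf = PerfusionConfig(
            F_in=p.get("F_in", base_perf.F_in),
            F_out=p.get("F_out", base_perf.F_out),
            C0=base_perf.C0,
            mu_blood=base_perf.mu_blood,
        )
        growth = GrowthLaw(mu_max=p.get("mu", base_growth.mu_max),
                           mode="constant")
        traj = simulate_arm(
            scenario, model=model, perf=perf, growth=growth, config=config,
            V_tumor0_mm3=V_tumor0_mm3,
        )
        return np.interp(series.times, traj.times_day, traj.V_tumor)

    return simulator


def default_fit_spec(seed: int = 0, multi_start: int = 5) -> FitSpec:
    """Fit F_in, F_out and mu with the calibrated values as p0."""
    return FitSpec(
        bounds={"F_in": (0.3, 30.0), "F_out": (0.3, 30.0),
                "mu": (2e-4, 8e-3)},
        p0={"F_in": 3.0, "F_out": 3.0, "mu": 1.52e-3},
        multi_start=multi_start,
        seed=seed,
    )


def time_to_plateau(
    times_day: np.ndarray,
    volumes: np.ndarray,
    weekly_threshold: float = 0.01,
) -> float | None:
    """First day from which every subsequent 7-day relative change stays
    below the threshold; None if the curve never settles."""
    times_day = np.asarray(times_day, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    for t in times_day:
        later = times_day >= t
        t_l, v_l = times_day[later], volumes[later]
        ok = True
        checked = 0
        for j, tj in enumerate(t_l):
            if tj + 7.0 > t_l[-1] + 1e-9:
                break
            checked += 1
            v_week = np.interp(tj + 7.0, t_l, v_l)
            if abs(v_week - v_l[j]) / max(v_l[j], 1e-12) > weekly_threshold:
                ok = False
                break
        if ok and checked > 0:
            return float(t)
    return None


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "arms": ["pbs", "metablocs_full"],
    "t0_day": 10.0,
    "t_end_day": 59.0,
    "t_start_treatment": 12.0,
    "cutsets": True,
    "target": "Vgrowth",
    "network": None,        # path; None = packaged reconstruction
    "fit_data": None,       # path to a cohort CSV; None = skip fitting
    "fit_arm": "pbs",
    "seed": 0,
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(config or {})
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(DEFAULT_CONFIG)
    merged.update(user)
    return merged


def run_pipeline(config, outdir: str | Path, seed: int | None = None) -> Path:
    """Run arms, structural report and (optionally) a fit; write artifacts.

    Writes per-arm trajectory CSVs, a cut-set TSV, a summary table and a
    provenance log; returns the run directory.
    """
    cfg = _load_config(config)
    if seed is not None:
        cfg["seed"] = seed
    if not cfg["arms"]:
        raise ValueError("no scenarios: config lists zero arms")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net = (load_network(cfg["network"]) if cfg["network"]
           else load_default_network())
    model = load_default_model(net)

    summary_rows = []
    errors: dict[str, str] = {}
    for arm in cfg["arms"]:
        try:
            scenario = build_scenario(
                arm,
                t0_day=cfg["t0_day"],
                t_end_day=cfg["t_end_day"],
                t_start_treatment=cfg["t_start_treatment"],
            )
            traj = simulate_arm(scenario, model=model)
            traj.to_csv(outdir / f"trajectory_{arm}.csv")
            plateau = time_to_plateau(traj.times_day, traj.V_tumor)
            # "late" = the post-plateau-onset window (days 40-50 of the
            # standard 59-day protocol), where lactate uptake shows up
            late = ((traj.times_day >= cfg["t_end_day"] - 19.0)
                    & (traj.times_day <= cfg["t_end_day"] - 9.0))
            summary_rows.append({
                "arm": arm,
                "final_V_tumor_mm3": float(traj.V_tumor[-1]),
                "plateau_day": plateau if plateau is not None else np.nan,
                "late_VLDH_mean": float(traj.flux("VLDH")[late].mean()),
                "late_nad_ratio": float(traj.nad_ratio[-1]),
            })
        except ValueError as err:
            errors[arm] = str(err)
    if not summary_rows:
        raise RuntimeError(f"all scenarios failed: {errors}")

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)

    if cfg["cutsets"]:
        cuts = minimal_cut_sets(net, cfg["target"])
        write_cut_set_report(cuts, outdir / "cutsets.tsv")
        ess = essential_reactions(net, cfg["target"])
        (outdir / "essential_reactions.txt").write_text(
            "\n".join(ess) + "\n", encoding="utf-8"
        )

    if cfg["fit_data"]:
        data = CohortSeries.from_csv(cfg["fit_data"], arm=cfg["fit_arm"])
        sim = make_volume_simulator(cfg["fit_arm"], model=model)
        result = fit(default_fit_spec(seed=cfg["seed"]), data, sim)
        (outdir / "fit_report.txt").write_text(
            result.report() + "\n", encoding="utf-8"
        )

    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    log = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "scenario_errors": errors,
    }
    (outdir / "run_log.json").write_text(
        json.dumps(log, indent=2, default=str) + "\n", encoding="utf-8"
    )
    return outdir


def compare_arms(run_dir: str | Path) -> pd.DataFrame:
    """Arm comparison table from a completed run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.tsv"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.tsv under {run_dir}")
    summary = pd.read_csv(summary_path, sep="\t")
    if len(summary) < 2:
        raise ValueError("compare_arms needs at least two completed arms")
    summary["plateaued"] = summary["plateau_day"].notna()
    summary["late_VLDH_sign"] = np.sign(summary["late_VLDH_mean"]).astype(int)
    return summary
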