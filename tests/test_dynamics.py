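import numpy as np
import pytest

from tumorflux.dynamics import (
    DeathLaw,
    DosingSchedule,
    GrowthLaw,
    PerfusionConfig,
    SimulationConfig,
    TumorState,
    death_rate,
    default_death,
    default_growth,
    default_initial_state,
    default_perfusion,
    derivatives,
    simulate,
    volume_of_cells,
)
from tumorflux.kinetics import KineticModel, RateLaw

from conftest import at_day


class TestDeathRate:
    def test_zero_at_unit_ratio(self):
        law = DeathLaw(k_d=0.37, n=3.0, k_ratio=2.2)
        assert death_rate(1.0, 1.0, law) == pytest.approx(0.0)

    def test_low_ratio_limit(self):
        law = DeathLaw(k_d=0.01, n=2.0, k_ratio=0.5)
        # rho -> 0: k_d / k_ratio^n
        assert death_rate(1e-9, 1.0, law) == pytest.approx(0.04, rel=1e-6)

    def test_hand_value(self):
        law = DeathLaw(k_d=0.01, n=2.0, k_ratio=1.0)
        assert death_rate(0.5, 1.0, law) == pytest.approx(0.006)

    def test_anti_death_above_unit_ratio(self):
        law = DeathLaw(k_d=0.01, n=2.0, k_ratio=1.0)
        assert death_rate(3.0, 1.0, law) < 0.0

    def test_singular_ratio_rejected(self):
        law = DeathLaw(k_d=0.01)
        with pytest.raises(ValueError):
            death_rate(1.0, 0.0, law)


class TestVolumeOfCells:
    def test_zero(self):
        assert volume_of_cells(0.0) == 0.0

    def test_default_constant(self):
        # 1e9 cells (X = 1000 in 1e6-cell units) occupy 1 cm^3
        assert volume_of_cells(1000.0) == pytest.approx(1000.0)

    def test_linearity(self):
        assert volume_of_cells(2 * 37.0) == pytest.approx(2 * volume_of_cells(37.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            volume_of_cells(-1.0)


def _quiet_model(net, model):
    """Model with all vmax = 0 (no reactions run)."""
    laws = {rid: RateLaw(rid, 0.0, dict(law.km), 0.0)
            for rid, law in model.rate_laws.items()}
    return KineticModel(net, laws, [])


class TestDerivatives:
    def test_all_sources_off_gives_zero_dC(self, net, model):
        quiet = _quiet_model(net, model)
        perf = PerfusionConfig(F_in=0.0, F_out=0.0,
                               C0=np.zeros(len(net.blood_ids)), mu_blood=0.0)
        state = TumorState(
            C=np.full(len(net.blood_ids), 0.5),
            m=np.full(len(net.cell_ids), 0.5),
            X=10.0, V_blood=0.1, V_tumor=110.0,
        )
        dy = derivatives(state, quiet, perf,
                         GrowthLaw(0.0, mode="constant"), DeathLaw(0.0))
        np.testing.assert_allclose(dy[: len(net.blood_ids)], 0.0)

    def test_capillary_expansion_terms(self, net, model):
        quiet = _quiet_model(net, model)
        perf = PerfusionConfig(F_in=0.0, F_out=0.0,
                               C0=np.zeros(len(net.blood_ids)), mu_blood=0.01)
        state = TumorState(
            C=np.zeros(len(net.blood_ids)),
            m=np.full(len(net.cell_ids), 0.5),
            X=0.0, V_blood=2.0, V_tumor=2000.0,
        )
        dy = derivatives(state, quiet, perf,
                         GrowthLaw(0.0, mode="constant"), DeathLaw(0.0))
        dVb, dVt = dy[-2], dy[-1]
        assert dVb == pytest.approx(0.02)          # mL/h
        assert dVt == pytest.approx(0.02 * 1000.0)  # same rate in mm^3/h

    def test_nonpositive_blood_volume_rejected(self, net, model):
        state = TumorState(
            C=np.zeros(len(net.blood_ids)), m=np.ones(len(net.cell_ids)),
            X=1.0, V_blood=0.0, V_tumor=1.0,
        )
        with pytest.raises(ValueError):
            derivatives(state, model, default_perfusion(net),
                        default_growth(), default_death())

    def test_finite_difference_matches_integrator(self, net, model):
        """(state(t+h) - state(t))/h from the solver approaches the RHS."""
        rng = np.random.default_rng(5)
        perf = default_perfusion(net)
        growth, death = default_growth(), default_death()
        for _ in range(3):
            state = TumorState(
                C=perf.C0 * rng.uniform(0.3, 1.0, len(net.blood_ids)),
                m=rng.uniform(0.05, 2.0, len(net.cell_ids)),
                X=float(rng.uniform(50, 500)),
                V_blood=float(rng.uniform(0.01, 0.1)),
                V_tumor=float(rng.uniform(100, 600)),
            )
            dy = derivatives(state, model, perf, growth, death)
            from scipy.integrate import solve_ivp

            def rhs(t, y):
                s = TumorState.unpack(y, len(net.blood_ids), len(net.cell_ids))
                return derivatives(s, model, perf, growth, death)

            # Richardson-extrapolated forward difference: the blood washout
            # modes are fast, so plain (y(h)-y0)/h is only first-order
            h = 1e-4  # hours
            fds = []
            for step in (h, h / 2):
                sol = solve_ivp(rhs, (0, step), state.pack(),
                                rtol=1e-11, atol=1e-13)
                fds.append((sol.y[:, -1] - state.pack()) / step)
            fd = 2 * fds[1] - fds[0]
            scale = np.maximum(np.abs(dy), 1e-6)
            np.testing.assert_allclose(fd / scale, dy / scale, atol=1e-3)


class TestClosedForms:
    def test_blood_volume_grows_exponentially(self, net, model):
        quiet = _quiet_model(net, model)
        mu_b = 2e-3
        perf = PerfusionConfig(F_in=0.0, F_out=0.0,
                               C0=np.zeros(len(net.blood_ids)), mu_blood=mu_b)
        state0 = TumorState(
            C=np.zeros(len(net.blood_ids)), m=np.ones(len(net.cell_ids)),
            X=10.0, V_blood=0.05, V_tumor=60.0,
        )
        traj = simulate(quiet, perf, GrowthLaw(0.0, mode="constant"),
                        DeathLaw(0.0), state0, DosingSchedule(12.0, {}),
                        10.0, 20.0)
        t_h = (traj.times_day - 10.0) * 24.0
        np.testing.assert_allclose(
            traj.V_blood, 0.05 * np.exp(mu_b * t_h), rtol=1e-5
        )

    def test_growth_dilution_closed_form(self, net, model):
        """With r = 0, m(t) = (m0 + eps) exp(-mu t) - eps exactly."""
        quiet = _quiet_model(net, model)
        mu = 3e-3
        eps = 0.2
        perf = PerfusionConfig(F_in=0.0, F_out=0.0,
                               C0=np.zeros(len(net.blood_ids)), mu_blood=0.0)
        m0 = np.linspace(0.5, 2.0, len(net.cell_ids))
        state0 = TumorState(
            C=np.zeros(len(net.blood_ids)), m=m0.copy(),
            X=10.0, V_blood=0.05, V_tumor=60.0,
        )
        traj = simulate(quiet, perf,
                        GrowthLaw(mu, mode="constant", eps_m=eps),
                        DeathLaw(0.0), state0, DosingSchedule(12.0, {}),
                        10.0, 20.0)
        t_h = (traj.times_day - 10.0) * 24.0
        expected = (m0[None, :] + eps) * np.exp(-mu * t_h)[:, None] - eps
        np.testing.assert_allclose(traj.m, np.maximum(expected, 0.0),
                                   rtol=1e-5, atol=1e-8)

    def test_zero_cells_stay_zero(self, net, model):
        perf = default_perfusion(net)
        state0 = default_initial_state(net, perf=perf)
        state0.X = 0.0
        state0.V_tumor = state0.V_blood * 1000.0
        traj = simulate(model, perf, default_growth(), default_death(),
                        state0, DosingSchedule(12.0, {}), 10.0, 25.0)
        np.testing.assert_allclose(traj.X, 0.0, atol=1e-9)
        # tumor volume then tracks the capillary volume alone
        np.testing.assert_allclose(
            traj.V_tumor, traj.V_blood * 1000.0, rtol=1e-5
        )


class TestBloodMassBalance:
    def test_conservation_with_static_capillaries(self, net, model):
        """With mu_blood = 0: d(C V_b)/dt = S_c r X + (C0 F_in - C F_out)."""
        perf = default_perfusion(net)
        perf = PerfusionConfig(perf.F_in, perf.F_out, perf.C0, mu_blood=0.0)
        state0 = default_initial_state(net, perf=perf)
        cfg = SimulationConfig(points_per_day=192)
        traj = simulate(model, perf, default_growth(), default_death(),
                        state0, DosingSchedule(12.0, {}), 10.0, 12.0,
                        config=cfg)
        t_h = traj.times_day * 24.0
        # integral form, starting after the fast initial washout transient
        k0 = int(np.searchsorted(traj.times_day, 10.5))
        influx = (net.S_c @ traj.r.T * traj.X
                  + (perf.C0[:, None] * perf.F_in
                     - traj.C.T * perf.F_out))
        total = traj.C * traj.V_blood[:, None]    # mmol in the capillaries
        gained = total[-1] - total[k0]
        integral = np.trapezoid(influx[:, k0:], t_h[k0:], axis=1)
        scale = np.maximum(np.abs(total[k0]) + np.abs(gained), 1e-3)
        np.testing.assert_allclose(gained / scale, integral / scale,
                                   atol=5e-3)


class TestSimulate:
    def test_output_grid_and_shapes(self, control_traj, net):
        assert control_traj.times_day[0] == pytest.approx(10.0)
        assert control_traj.times_day[-1] == pytest.approx(59.0)
        assert np.all(np.diff(control_traj.times_day) > 0)
        # at least one point per day, plus state/flux blocks of full width
        assert len(control_traj.times_day) >= 49
        assert control_traj.C.shape[1] == len(net.blood_ids)
        assert control_traj.m.shape[1] == len(net.cell_ids)
        assert control_traj.r.shape[1] == len(net.reactions)

    def test_csv_column_order(self, control_traj, net, tmp_path):
        path = tmp_path / "traj.csv"
        control_traj.to_csv(path)
        header = path.read_text().splitlines()[0].split(",")
        expected = (["time_day"]
                    + [f"C_{s}" for s in net.blood_ids]
                    + [f"m_{s}" for s in net.cell_ids]
                    + ["X_1e6cells", "V_blood_mL", "V_tumor_mm3"]
                    + [f"r_{r}" for r in net.reaction_ids])
        assert header == expected

    def test_invalid_window_rejected(self, net, model):
        perf = default_perfusion(net)
        with pytest.raises(ValueError):
            simulate(model, perf, default_growth(), default_death(),
                     default_initial_state(net, perf=perf),
                     DosingSchedule(12.0, {}), 20.0, 20.0)

    def test_drugs_wash_into_blood(self, therapy_traj, net):
        """Inlet dosing raises the blood drug concentration after day 12."""
        metf = therapy_traj.blood("METF")
        assert at_day(therapy_traj, 11, metf) == pytest.approx(0.0, abs=1e-9)
        assert at_day(therapy_traj, 14, metf) == pytest.approx(1.0, rel=0.05)

    def test_metformin_dose_monotonicity(self, net, model):
        """Final tumor volume is non-increasing in metformin exposure."""
        finals = []
        perf = default_perfusion(net)
        for dose in [0.0, 0.1, 1.0]:
            doses = {"LA": 0.5, "HCIT": 0.5, "METF": dose}
            traj = simulate(model, perf, default_growth(), default_death(),
                            default_initial_state(net, perf=perf),
                            DosingSchedule(12.0, doses), 10.0, 59.0)
            finals.append(traj.V_tumor[-1])
        assert finals[0] >= finals[1] >= finals[2]
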