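"""Multiphase solver verification: equilibria, Poiseuille limit, conservation."""

import numpy as np
import pytest

from tumorperf import geometry as g
from tumorperf import solver as sv
from tumorperf.constitutive import PhaseSpec, default_tumor_phases

PLASMA = [PhaseSpec("plasma", "primary", 1030.0, "constant", 0.001)]
DP = 3325.0 - 2128.0  # driving pressure difference, Pa


def straight_channel(h=0.5, L=40.0, H=10.0):
    geo = g.build_vessel_geometry(g.VesselGeometryConfig(
        vessel_length=L, vessel_height=H, depression_depth=0.0))
    return g.rasterize(geo, h)


def poiseuille_run(h=0.5, steps=50, H=10.0, L=40.0):
    mask = straight_channel(h, L, H)
    bcs = sv.BoundaryConditionSet(3325.0, 2128.0, {"plasma": 1.0})
    conf = sv.SolverConfig(dt=1e-4, end_time=steps * 1e-4)
    snaps, rlog = sv.run_transient(mask, PLASMA, bcs, conf,
                                   snapshot_times=())
    return snaps[max(snaps)], rlog, mask


def test_cfl_advisory_warns_but_does_not_fail():
    import warnings as w
    mask = straight_channel(0.5, 20.0, 10.0)
    bcs = sv.BoundaryConditionSet(3325.0, 2128.0, {"plasma": 1.0})
    st = sv.initial_state(mask, PLASMA, bcs)
    for _ in range(5):  # let the flow spin up past the CFL threshold
        st = sv.advance(st, mask, PLASMA, bcs, sv.SolverConfig(dt=1e-4))
    with w.catch_warnings(record=True) as rec:
        w.simplefilter("always")
        sv.advance(st, mask, PLASMA, bcs, sv.SolverConfig(dt=1e-4))
    assert any("CFL" in str(r.message) for r in rec)


class TestEquilibriaAndSymmetry:
    def test_quiescent_state_is_a_fixed_point(self):
        mask = straight_channel()
        bcs = sv.BoundaryConditionSet(2128.0, 2128.0, {"plasma": 1.0})
        st0 = sv.initial_state(mask, PLASMA, bcs)
        st1 = sv.advance(st0, mask, PLASMA, bcs, sv.SolverConfig(dt=1e-4))
        assert np.abs(st1.u["plasma"]).max() < 1e-10
        assert np.abs(st1.v["plasma"]).max() < 1e-10
        assert np.abs(st1.psi["plasma"] - st0.psi["plasma"]).max() < 1e-10

    def test_two_identical_phases_move_together(self):
        mask = straight_channel()
        phases = [PhaseSpec("a", "primary", 1030.0, "constant", 0.001),
                  PhaseSpec("b", "secondary", 1030.0, "constant", 0.001, 7e-6)]
        bcs = sv.BoundaryConditionSet(3325.0, 2128.0, {"a": 0.5, "b": 0.5})
        st = sv.initial_state(mask, phases, bcs, {"a": 0.5, "b": 0.5})
        conf = sv.SolverConfig(dt=1e-4)
        for _ in range(10):
            st = sv.advance(st, mask, phases, bcs, conf)
        assert np.abs(st.u["a"] - st.u["b"]).max() < 1e-8
        assert np.abs(st.v["a"] - st.v["b"]).max() < 1e-8

    def test_drag_sources_sum_to_zero(self):
        """Momentum exchanged between phase pairs is equal and opposite.

        Uses a blood-like pair (drag coefficient ~1e7): for the near-rigid
        plasma/air coupling (~1e14) the identity still holds but is only
        observable to the round-off of the much larger opposing forces.
        """
        mask = straight_channel(1.0, 10.0, 5.0)
        phases = [PhaseSpec("plasma", "primary", 1030.0, "constant", 0.001),
                  PhaseSpec("rbc", "secondary", 1100.0, "constant", 6e-3,
                            7e-6)]
        bcs = sv.BoundaryConditionSet(3000.0, 2780.0,
                                      {"plasma": 0.55, "rbc": 0.45})
        st = sv.initial_state(mask, phases, bcs,
                              {"plasma": 0.55, "rbc": 0.45})
        rng = np.random.RandomState(0)
        ustar = {n: rng.randn(*st.u[n].shape) * 1e-3 for n in st.u}
        vstar = {n: rng.randn(*st.v[n].shape) * 1e-3 for n in st.v}
        ws = sv._workspace(mask, phases, bcs)
        gdot = sv.shear_rate_field(st, mask)
        eta = {"plasma": np.full((mask.nx, mask.ny), 1e-3),
               "rbc": np.full((mask.nx, mask.ny), 6e-3)}
        uo, vo, _, _ = sv._drag_couple(ws, st, ustar, vstar, gdot, eta,
                                       1e-4, 1e-6)
        # sum_i rho_i Psi_i (v_out - v_in) / dt = total drag impulse = 0
        for comp, star, out in (("u", ustar, uo), ("v", vstar, vo)):
            unk = ws.mom[comp]["unk"]
            fi, fj = unk[:, 0], unk[:, 1]
            favg = sv._face_avg_u if comp == "u" else sv._face_avg_v
            tot = np.zeros(len(fi))
            scale = np.zeros(len(fi))
            for ph in phases:
                w = ph.density * np.maximum(favg(st.psi[ph.name])[fi, fj],
                                            1e-6)
                dv = out[ph.name][fi, fj] - star[ph.name][fi, fj]
                tot += w * dv
                scale += w * np.abs(dv)
            assert np.abs(tot).max() <= 1e-9 * max(scale.max(), 1e-30)


class TestPoiseuilleLimit:
    def test_parabolic_profile_recovered(self):
        st, rlog, mask = poiseuille_run()
        u = st.u["plasma"]
        prof = u[u.shape[0] // 2, 1:-1]
        ratio = prof.max() / prof.mean()
        assert ratio == pytest.approx(1.5, rel=0.02)
        umax_theory = DP * (10e-6) ** 2 / (8 * 0.001 * 40e-6)
        assert prof.max() == pytest.approx(umax_theory, rel=0.05)

    def test_mass_balance_and_fraction_sum(self):
        st, rlog, mask = poiseuille_run()
        assert max(e["mass_balance_error"] for e in rlog) <= 1e-6
        openc = mask.is_open()
        assert np.abs(st.psi["plasma"][openc] - 1.0).max() <= 1e-8

    def test_error_decreases_under_grid_refinement(self):
        errs = []
        for h in (1.0, 0.5, 0.25):
            st, _, _ = poiseuille_run(h=h, steps=30)
            u = st.u["plasma"]
            prof = u[u.shape[0] // 2, 1:-1]
            errs.append(abs(prof.max() / prof.mean() - 1.5))
        assert errs[0] > errs[1] > errs[2]


class TestMultiphaseConservation:
    def test_two_phase_mass_balance_and_bounds(self, constant_probe):
        """Drag-coupled plasma/air perfusion conserves mixture mass per step."""
        from tumorperf import pipeline as tp
        cfg = tp.ExperimentConfig(
            tumor_width=3.0, tumor_height=3.0, fiber_circles=(),
            tumor_cell_size=0.125, end_time=5e-3, snapshot_times=(5e-3,))
        res = tp.run_tumor_stage(3, constant_probe, cfg)
        assert max(e["mass_balance_error"] for e in res.residual_log) <= 1e-6
        st = res.snapshots[5e-3]
        openc = res.mask.is_open()
        tot = st.psi["plasma"] + st.psi["air"]
        assert np.abs(tot[openc] - 1.0).max() <= 1e-8
        for n in ("plasma", "air"):
            assert st.psi[n][openc].min() >= -1e-12
            assert st.psi[n][openc].max() <= 1 + 1e-12


class TestBoundaryConditions:
    def test_ghost_pressures_and_inlet_fractions(self):
        mask = straight_channel()
        phases = [PhaseSpec("plasma", "primary", 1030.0, "constant", 0.001),
                  PhaseSpec("rbc", "secondary", 1100.0, "constant", 6e-3,
                            7e-6),
                  PhaseSpec("wbc", "secondary", 1080.0, "constant", 0.011,
                            14e-6)]
        fr = {"plasma": 0.54, "rbc": 0.45, "wbc": 0.01}
        bcs = sv.BoundaryConditionSet(
            3325.0, 2128.0, fr, {"plasma": 0.0, "rbc": 1.0, "wbc": 0.0})
        st = sv.initial_state(mask, phases, bcs, fr)
        ws = sv._workspace(mask, phases, bcs)
        assert np.all(st.p[ws.inlet] == 3325.0)
        assert np.all(st.p[ws.outlet] == 2128.0)
        for n, f in fr.items():
            assert np.all(st.psi[n][ws.inlet] == f)
        # outlet ghost cells carry the backflow fractions (used only when
        # the local face velocity points inward)
        assert np.all(st.psi["rbc"][ws.outlet] == 1.0)
        assert np.all(st.psi["wbc"][ws.outlet] == 0.0)

    def test_backflow_fractions_unused_under_outflow(self):
        st, _, mask = poiseuille_run(steps=30)
        openc = mask.is_open()
        # flow is everywhere outward at the outlet; interior composition
        # remains pure plasma
        assert np.abs(st.psi["plasma"][openc] - 1.0).max() <= 1e-8

    def test_snapshot_time_outside_run_rejected(self):
        mask = straight_channel()
        bcs = sv.BoundaryConditionSet(3325.0, 2128.0, {"plasma": 1.0})
        conf = sv.SolverConfig(dt=1e-4, end_time=1e-3)
        with pytest.raises(ValueError, match="snapshot"):
            sv.run_transient(mask, PLASMA, bcs, conf, snapshot_times=(0.5,))

    def test_zero_end_time_returns_initial_state_only(self):
        mask = straight_channel()
        bcs = sv.BoundaryConditionSet(3325.0, 2128.0, {"plasma": 1.0})
        conf = sv.SolverConfig(dt=1e-4, end_time=0.0)
        snaps, rlog = sv.run_transient(mask, PLASMA, bcs, conf,
                                       snapshot_times=())
        assert list(snaps) == [0.0]
        assert rlog == []


class TestConvergenceClassifier:
    def test_all_zero_residuals_converged(self):
        log = [{"res_continuity": 0.0, "res_velocity": 0.0}] * 12
        assert sv.check_convergence(log)["status"] == "converged"

    def test_residual_above_tolerance_not_converged(self):
        log = [{"res_continuity": 1e-3, "res_velocity": 0.0}]
        out = sv.check_convergence(log, tol_continuity=1e-4)
        assert out["status"] == "not_converged"

    def test_oscillation_around_tolerance_is_marginal(self):
        log = [{"res_continuity": (2e-4 if k % 2 else 5e-5),
                "res_velocity": 0.0} for k in range(10)]
        log.append({"res_continuity": 5e-5, "res_velocity": 0.0})
        out = sv.check_convergence(log, tol_continuity=1e-4)
        assert out["status"] == "marginal"
        assert out["violations"] == 5

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            sv.check_convergence([])
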