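"""Domain construction, noise generation, stepping contracts and record
round-trips."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from epileptor2d import (ModelParameters, Simulator, SimulationRecord,
                         build_domain, generate_noise)
from epileptor2d import config as cfg_mod, engine
from epileptor2d.dynamics import rest_state_residual


def small_domain(nx=16, ny=16, **kw):
    width = nx * 0.075
    height = ny * 0.075
    kw.setdefault("excitation_center", (width / 2, height / 2))
    return build_domain(width=width, height=height, nx=nx, ny=ny, **kw)


class TestBuildDomain:
    def test_default_geometry(self):
        dom = build_domain()
        assert dom.shape == (80, 80)
        assert dom.dx == pytest.approx(0.075)
        # disk membership by brute-force cell-centre distance
        X, Y = dom.cell_centers()
        brute = ((X - 3.0) ** 2 + (Y - 3.0) ** 2 <= 0.3 ** 2).sum()
        assert (dom.Gsyn_map == 5.0).sum() == brute
        assert brute == pytest.approx(np.pi * 0.3 ** 2 / 0.075 ** 2, abs=3)

    def test_zero_radius_elevates_nothing(self):
        dom = build_domain(excitation_radius=0.0)
        assert (dom.Gsyn_map == 5.0).sum() == 0

    def test_zoned_bath_map(self):
        dom = build_domain(Kbath_center=7.0, Kbath_periphery=4.0)
        assert dom.Kbath_map.max() == 7.0
        assert dom.Kbath_map.min() == 4.0
        assert (dom.Kbath_map == 7.0).sum() == (dom.Gsyn_map == 5.0).sum()

    def test_disk_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            build_domain(excitation_center=(10.0, 3.0))

    def test_default_probes(self):
        dom = build_domain()
        labels = [p[0] for p in dom.probes]
        assert labels == ["S1", "S2"]
        # S2 sits 2 mm from the centre
        assert dom.probes[1][1] - dom.probes[0][1] == pytest.approx(2.0)


class TestGenerateNoise:
    def test_homogeneous_is_a_single_shared_draw(self):
        rng = np.random.default_rng(0)
        field = generate_noise("homogeneous", (20, 20), rng)
        assert np.ptp(field) == 0.0

    def test_inhomogeneous_statistics(self):
        rng = np.random.default_rng(1)
        field = generate_noise("inhomogeneous", (80, 80), rng)
        n = field.size
        assert abs(field.mean()) < 3 / np.sqrt(n)
        assert abs(field.var() - 1.0) < 3 * np.sqrt(2.0 / n)

    def test_reproducible_given_seed(self):
        a = generate_noise("inhomogeneous", (10, 10), np.random.default_rng(7))
        b = generate_noise("inhomogeneous", (10, 10), np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestStep:
    def test_quiescent_step_matches_independent_rest_integration(self):
        """With sigma = 0 and no firing, the grid step tracks the
        two-variable rest ODE integrated independently."""
        p = ModelParameters(sigma_over_gL=0.0, model_variant=1)
        dom = small_domain()
        sim = Simulator(dom, p)
        state = sim.initial_state()
        rng = np.random.default_rng(0)
        for _ in range(1000):  # 1 s
            state = sim.step(state, rng)
        sol = solve_ivp(lambda _, y: rest_state_residual(y, p), (0, 1.0),
                        [p.K_o0, p.Na_i0], rtol=1e-10, atol=1e-12)
        assert np.allclose(state.K_o, sol.y[0, -1], atol=1e-3)
        assert np.allclose(state.Na_i, sol.y[1, -1], atol=1e-3)
        # V tracks the slow potassium depolarization, far below threshold
        u_now = 26.6 * np.log(state.K_o / p.K_o0)
        assert np.allclose(state.V, u_now, atol=1e-2)
        assert np.allclose(state.x_D, 1.0)

    def test_variant3_with_zero_diffusion_matches_variant2_bitwise(self):
        cfg2 = {"model": {"variant": 2},
                "run": {"seed": 5, "total_time": 3.0}}
        cfg3 = {"model": {"variant": 3}, "parameters": {"D_K": 0.0},
                "run": {"seed": 5, "total_time": 3.0}}
        rec2 = engine.run(cfg_mod.load_and_validate(cfg2))
        rec3 = engine.run(cfg_mod.load_and_validate(cfg3))
        assert np.array_equal(rec2.probes["S1"], rec3.probes["S1"])
        assert np.array_equal(rec2.snap_K, rec3.snap_K)

    def test_pure_diffusion_conserves_mass(self):
        """All reaction terms off: total potassium is conserved to machine
        precision per step and to < 1e-9 relative over 1e4 steps."""
        p = ModelParameters(sigma_over_gL=0.0, rho=0.0, tau_K=1e12,
                            V_th=1e6, model_variant=1)
        dom = small_domain(Gsyn_center=0.0, Gsyn_periphery=0.0)
        sim = Simulator(dom, p)
        state = sim.initial_state()
        state.K_o[8, 8] += 50.0  # point perturbation
        total0 = state.K_o.sum()
        rng = np.random.default_rng(0)
        state = sim.step(state, rng)
        assert state.K_o.sum() == pytest.approx(total0, abs=1e-9)
        for _ in range(9999):
            state = sim.step(state, rng)
        assert abs(state.K_o.sum() - total0) / total0 < 1e-9

    def test_determinism(self):
        cfg = cfg_mod.load_and_validate({"run": {"seed": 9,
                                                 "total_time": 2.0}})
        rec_a = engine.run(cfg)
        rec_b = engine.run(cfg)
        assert np.array_equal(rec_a.probes["S1"], rec_b.probes["S1"])
        assert np.array_equal(rec_a.ray_K, rec_b.ray_K)

    def test_nonfinite_field_aborts_with_diagnostic(self):
        p = ModelParameters(model_variant=1)
        sim = Simulator(small_domain(), p)
        state = sim.initial_state()
        state.Na_i[3, 4] = np.inf
        with pytest.raises(FloatingPointError, match=r"Na_i.*\(3, 4\)"):
            sim.step(state, np.random.default_rng(0))

    def test_diffusion_stability_guard(self):
        p = ModelParameters(D_K=4e-4, model_variant=1)
        with pytest.raises(ValueError, match="unstable"):
            Simulator(small_domain(), p, dt=5.0)


class TestRun:
    def test_zero_time_records_only_initial_state(self):
        cfg = cfg_mod.load_and_validate({"run": {"seed": 1,
                                                 "total_time": 0.0}})
        rec = engine.run(cfg)
        assert rec.t_probe.shape == (1,)
        assert rec.snap_K.shape[0] == 1
        assert rec.probes["S1"][0, 0] == pytest.approx(3.0)   # K_o0
        assert rec.probes["S1"][0, 3] == pytest.approx(1.0)   # x_D

    def test_timestamps_strictly_increasing(self):
        cfg = cfg_mod.load_and_validate({"run": {"seed": 1,
                                                 "total_time": 1.0}})
        rec = engine.run(cfg)
        assert np.all(np.diff(rec.t_probe) > 0)
        assert np.all(np.diff(rec.ray_t) > 0)

    def test_record_roundtrip(self, tmp_path):
        cfg = cfg_mod.load_and_validate({"run": {"seed": 3,
                                                 "total_time": 1.0}})
        rec = engine.run(cfg)
        rec.save(tmp_path / "rec")
        back = SimulationRecord.load(tmp_path / "rec")
        assert back.seed == rec.seed
        assert back.model_variant == rec.model_variant
        assert np.allclose(back.probes["S1"], rec.probes["S1"])
        assert np.allclose(back.snap_K, rec.snap_K)
        assert back.config_echo == rec.config_echo

    def test_roi_capture(self):
        cfg = cfg_mod.load_and_validate({
            "recording": {"roi_window": [0.2, 0.6]},
            "run": {"seed": 1, "total_time": 1.0}})
        rec = engine.run(cfg)
        assert rec.roi_V.shape[1] == 80
        assert rec.roi_t[0] >= 0.2
        assert rec.roi_t[-1] <= 0.6
        # burst-rate resolution: one sample per step
        assert np.allclose(np.diff(rec.roi_t), 1e-3)


class TestSweep:
    def test_single_value_equals_direct_run(self):
        from epileptor2d.analysis import front_arrival_times, wavefront_speed
        cfg = cfg_mod.load_preset("narrow_strip", seed=11)
        cfg.total_time = 100.0
        cfg.parameters["K_bath"] = 8.0  # faster ramp, earlier ignition
        cfg.validate()
        table = engine.sweep(cfg, "lambda_conn", [0.385])
        rec = engine.run(cfg)
        front = front_arrival_times(rec.ray_t, rec.ray_r, rec.ray_K)
        expect = wavefront_speed(front)
        assert table.loc[0, "speed"] == pytest.approx(expect.speed)
        assert table.loc[0, "error"] == ""

    def test_failed_run_is_flagged_not_raised(self):
        cfg = cfg_mod.load_preset("narrow_strip", seed=11)
        cfg.total_time = 1.0  # far too short for any wave
        table = engine.sweep(cfg, "lambda_conn", [0.385, 0.2])
        assert len(table) == 2
        assert (table["error"] != "").all()

    def test_unknown_parameter_rejected(self):
        cfg = cfg_mod.load_preset("narrow_strip")
        with pytest.raises(ValueError, match="sweep parameter"):
            engine.sweep(cfg, "tau_K", [100.0])
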