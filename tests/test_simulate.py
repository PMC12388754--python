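"""Forward simulators: closed forms, ODE integration, noise, configs."""

import numpy as np
import pytest

import foulfit as ff
from foulfit.crossflow import crossflow_flux_closed, crossflow_volume_closed
from foulfit.deadend import deadend_flux, deadend_volume
from foulfit.exceptions import ValidationError

from conftest import MECHANISMS


class TestBlockingParams:
    def test_jr_at_least_jo_rejected(self):
        with pytest.raises(ValidationError, match="JR"):
            ff.BlockingParams("complete", Jo=100, K=1, JR=100, family="crossflow")

    def test_deadend_with_removal_rejected(self):
        with pytest.raises(ValidationError, match="dead-end"):
            ff.BlockingParams("complete", Jo=100, K=1, JR=10, family="dead_end")

    @pytest.mark.parametrize("bad", [dict(Jo=0, K=1), dict(Jo=100, K=0)])
    def test_nonpositive_parameters_rejected(self, bad):
        with pytest.raises(ValidationError):
            ff.BlockingParams("complete", **bad)


class TestDeadendClosedForms:
    def test_complete_exponential_decay(self):
        p = ff.BlockingParams("complete", Jo=400, K=1.0)
        s = ff.simulate_deadend(p, [1.0])
        assert s.flux[0] == pytest.approx(400 * np.exp(-1.0), abs=5e-3)

    def test_intermediate_zero_fouling_limit(self):
        p = ff.BlockingParams("intermediate", Jo=400, K=1e-12)
        s = ff.simulate_deadend(p, np.linspace(0.1, 2, 10))
        np.testing.assert_allclose(s.flux, 400.0, rtol=1e-8)

    def test_standard_volume_closed_form(self):
        # (Ks·Jo/2) = 1 h⁻¹ with Jo=400 → Ks=0.005; v(1) = 400/(1+1) = 200
        p = ff.BlockingParams("standard", Jo=400, K=0.005)
        s = ff.simulate_deadend(p, [1.0])
        assert s.v[0] == pytest.approx(200.0)

    @pytest.mark.parametrize("mech", MECHANISMS)
    def test_volume_is_integral_of_flux(self, mech):
        # closed-form v(t) must agree with dense trapezoid quadrature of J
        k = {"complete": 0.8, "intermediate": 0.003, "standard": 0.003,
             "cake": 8e-6}[mech]
        t = np.linspace(1e-5, 1.0, 20001)
        j = deadend_flux(mech, t, 400.0, k)
        v = deadend_volume(mech, t, 400.0, k)
        quad = np.concatenate([[0], np.cumsum(0.5 * (j[1:] + j[:-1]) * np.diff(t))])
        np.testing.assert_allclose(v - v[0], quad, rtol=1e-6, atol=1e-6)


class TestCrossflowSimulation:
    def test_complete_matches_analytic_solution(self):
        jo, jr, k = 400.0, 60.0, 2.0
        p = ff.BlockingParams("complete", Jo=jo, K=k, JR=jr, family="crossflow")
        s = ff.simulate_crossflow(p, [0.5])
        expected = jr + (jo - jr) * np.exp(-k * 0.5)  # = 185.078...
        assert s.flux[0] == pytest.approx(expected, rel=1e-9)

    def test_complete_fixed_point_is_jr(self):
        jo, jr, k = 400.0, 60.0, 2.0
        assert crossflow_flux_closed("complete", 50.0, jo, k, jr) == (
            pytest.approx(jr, rel=1e-12)
        )

    def test_intermediate_matches_analytic_solution(self):
        jo, jr, k = 400.0, 60.0, 0.03
        c = (jo - jr) / jo
        t = np.linspace(0.1, 2, 8)
        expected = jr / (1 - c * np.exp(-k * jr * t))
        p = ff.BlockingParams("intermediate", Jo=jo, K=k, JR=jr, family="crossflow")
        s = ff.simulate_crossflow(p, t)
        np.testing.assert_allclose(s.flux, expected, rtol=1e-9)

    @pytest.mark.parametrize("mech,k", [("complete", 2.0), ("intermediate", 0.03)])
    def test_ode_matches_closed_form(self, mech, k, grid120):
        p = ff.BlockingParams(mech, Jo=400, K=k, JR=60, family="crossflow")
        ode = ff.simulate_crossflow(p, grid120, method="ode")
        closed = ff.simulate_crossflow(p, grid120, method="auto")
        np.testing.assert_allclose(ode.flux, closed.flux, rtol=1e-6)
        np.testing.assert_allclose(ode.v, closed.v, rtol=1e-6)

    @pytest.mark.parametrize("mech", MECHANISMS)
    def test_flux_decreasing_and_bounded_by_jr(self, mech, grid60):
        from conftest import crossflow_series

        s, _ = crossflow_series(mech, jr=60.0)
        assert np.all(np.diff(s.flux) < 0)
        assert np.all(s.flux >= 60.0 - 1e-9)

    def test_closed_form_volume_consistency(self):
        # analytic v(t) for n=1 equals dense quadrature of the analytic J
        jo, jr, k = 400.0, 60.0, 0.03
        t = np.linspace(1e-6, 1.5, 20001)
        j = crossflow_flux_closed("intermediate", t, jo, k, jr)
        v = crossflow_volume_closed("intermediate", t, jo, k, jr)
        quad = np.concatenate([[0], np.cumsum(0.5 * (j[1:] + j[:-1]) * np.diff(t))])
        np.testing.assert_allclose(v - v[0], quad, rtol=1e-7, atol=1e-6)

    def test_invalid_grid_rejected(self):
        p = ff.BlockingParams("complete", Jo=400, K=1, JR=0, family="crossflow")
        with pytest.raises(ValidationError):
            ff.simulate_crossflow(p, [0.0, 0.5])
        with pytest.raises(ValidationError):
            ff.simulate_crossflow(p, [0.5, 0.5])


class TestNoise:
    def test_zero_cv_is_identity(self, grid60):
        from conftest import deadend_series

        s, _ = deadend_series("complete")
        noisy = ff.add_noise(s, ff.NoiseSpec(cv=0.0, seed=1))
        assert noisy is s

    def test_seed_determinism(self):
        from conftest import deadend_series

        s, _ = deadend_series("complete")
        a = ff.add_noise(s, ff.NoiseSpec(cv=0.01, seed=1))
        b = ff.add_noise(s, ff.NoiseSpec(cv=0.01, seed=1))
        np.testing.assert_array_equal(a.flux, b.flux)
        c = ff.add_noise(s, ff.NoiseSpec(cv=0.01, seed=2))
        assert not np.array_equal(a.flux, c.flux)

    def test_empirical_noise_level(self):
        from conftest import deadend_series

        s, _ = deadend_series("complete")
        ratios = [
            ff.add_noise(s, ff.NoiseSpec(cv=0.05, seed=seed)).flux / s.flux
            for seed in range(1000)
        ]
        sd = np.std(np.concatenate(ratios))
        assert sd == pytest.approx(0.05, rel=0.10)

    def test_v_recomputed_from_noisy_flux(self):
        from conftest import deadend_series

        s, _ = deadend_series("complete")
        noisy = ff.add_noise(s, ff.NoiseSpec(cv=0.05, seed=3))
        from foulfit.flux import _trapz_volume

        np.testing.assert_allclose(noisy.v, _trapz_volume(noisy.times, noisy.flux))

    def test_negative_cv_rejected(self):
        with pytest.raises(ValidationError):
            ff.NoiseSpec(cv=-0.1, seed=0)


class TestCalibrateK:
    @pytest.mark.parametrize("mech", MECHANISMS)
    def test_depth_is_hit(self, mech):
        k = ff.calibrate_k(mech, 400.0, 90.0, 1.0, jr=60.0, family="crossflow")
        p = ff.BlockingParams(mech, Jo=400.0, K=k, JR=60.0, family="crossflow")
        s = ff.simulate_crossflow(p, [1.0])
        assert s.flux[0] == pytest.approx(90.0, rel=1e-6)


class TestSimulationConfig:
    def test_yaml_round_trip_and_fit(self, tmp_path):
        cfg = tmp_path / "sim.yaml"
        cfg.write_text(
            "mechanism: complete\nfamily: crossflow\nJo: 400\nK: 2.0\nJR: 60\n"
            "t_end: 60\ndt: 1\nnoise: {cv: 0.0, seed: 0}\n"
        )
        out = tmp_path / "sim.csv"
        ff.SimulationConfig.from_yaml(cfg).run_to_csv(out)
        series = ff.read_flux_csv(out)
        fit = ff.fit_crossflow(series, "complete", jo=400.0)
        # v is rebuilt by trapezoid from the CSV flux, so recovery is limited
        # by quadrature error on the 1-min grid, not by the regression
        assert fit.K == pytest.approx(2.0, rel=0.02)
        assert fit.JR_fit == pytest.approx(60.0, rel=0.02)

    def test_inadmissible_config_rejected(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("mechanism: complete\nfamily: dead_end\nJo: 400\nK: 1\nJR: 50\n")
        with pytest.raises(Exception):
            ff.SimulationConfig.from_yaml(cfg)
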