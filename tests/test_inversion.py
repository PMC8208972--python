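"""Loss arithmetic and optimiser behaviour on cheap objectives."""

import math

import numpy as np
import pytest

from istlung import (
    ISTMeasurement,
    OptimizerConfig,
    OptimizationResult,
    ThetaParams,
    benchmark_optimizers,
    observable_mismatch_loss,
    loss,
    minimize_objective,
    optimize,
    success_rate,
)
from istlung.exceptions import ConfigurationError, ForwardModelError, UndefinedInputError
from istlung.inversion import PARAM_NAMES, bounds_array, vector_to_theta


def _meas(elv180, elv60, qp180, qp60):
    return ISTMeasurement(elv180, elv60, qp180, qp60, 0.15)


class TestLossArithmetic:
    def test_worked_example(self):
        sim = _meas(1.1, 2.0, 3.0, 5.0)
        measured = _meas(1.0, 2.0, 3.0, 4.0)
        assert observable_mismatch_loss(sim, measured) == pytest.approx(0.35, abs=1e-12)

    def test_absolute_value_symmetry(self):
        measured = _meas(1.0, 2.0, 3.0, 4.0)
        below = observable_mismatch_loss(_meas(0.9, 2.0, 3.0, 4.0), measured)
        above = observable_mismatch_loss(_meas(1.1, 2.0, 3.0, 4.0), measured)
        assert below == pytest.approx(above, rel=1e-12)
        assert below == pytest.approx(0.1, abs=1e-12)

    def test_zero_iff_observables_match(self):
        measured = _meas(2.3, 2.1, 4.9, 4.7)
        assert observable_mismatch_loss(measured, measured) == 0.0
        assert observable_mismatch_loss(_meas(2.3, 2.1, 4.9, 4.71), measured) > 0

    def test_zero_at_generating_theta(self, settings, healthy_measurement,
                                      healthy_theta):
        assert loss(healthy_theta, healthy_measurement, settings) == 0.0

    def test_forward_failure_maps_to_inf(self, settings, healthy_measurement,
                                         monkeypatch):
        import istlung.inversion as inv

        def boom(*a, **k):
            raise ForwardModelError("nope")

        monkeypatch.setattr(inv, "run_ist", boom)
        assert math.isinf(loss(ThetaParams(2.0, 4.9), healthy_measurement, settings))


UNIT_BOX = np.array([[0.0, 1.0]] * 3)
CENTRE = np.array([0.3, 0.6, 0.5])


def _quadratic(x):
    return float(np.sum((x - CENTRE) ** 2))


class TestOptimizersOnToyObjective:
    def test_bayes_finds_quadratic_minimum(self):
        config = OptimizerConfig(method="bayes", n_iterations=50, seed=0)
        x, y, trace, n = minimize_objective(_quadratic, UNIT_BOX, config)
        assert np.all(np.abs(x - CENTRE) < 0.05)

    @pytest.mark.parametrize("method", ["bayes", "nelder_mead", "random"])
    def test_trace_monotone_nonincreasing(self, method):
        budget = 25 if method == "bayes" else 80
        config = OptimizerConfig(method=method, n_iterations=budget, seed=1)
        x, y, trace, n = minimize_objective(_quadratic, UNIT_BOX, config)
        assert np.all(np.diff(trace) <= 0)
        assert trace[-1] == pytest.approx(y)

    @pytest.mark.parametrize("method", ["bayes", "nelder_mead", "random"])
    def test_seeded_determinism(self, method):
        budget = 20 if method == "bayes" else 60
        config = OptimizerConfig(method=method, n_iterations=budget, seed=7)
        out1 = minimize_objective(_quadratic, UNIT_BOX, config)
        out2 = minimize_objective(_quadratic, UNIT_BOX, config)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[2], out2[2])

    def test_nelder_mead_beats_centre_start(self):
        config = OptimizerConfig(method="nelder_mead", n_iterations=120, seed=0)
        x, y, *_ = minimize_objective(_quadratic, UNIT_BOX, config)
        assert y < 1e-4


class TestSuccessRate:
    def _result(self, success):
        return OptimizationResult(
            theta_star=ThetaParams(2.0, 4.9), loss_star=0.01,
            loss_trace=np.array([0.01]), n_evaluations=1,
            success=success, seed=0, method="random",
        )

    def test_all_success(self):
        assert success_rate([self._result(True)] * 5) == 100.0

    def test_nineteen_of_twenty(self):
        results = [self._result(True)] * 19 + [self._result(False)]
        assert success_rate(results) == pytest.approx(95.0)

    def test_two_of_three(self):
        results = [self._result(True), self._result(False), self._result(True)]
        assert success_rate(results) == pytest.approx(66.6667, abs=1e-3)

    def test_empty_list_undefined(self):
        with pytest.raises(UndefinedInputError):
            success_rate([])


def _fake_run_ist(theta, settings, **kwargs):
    """Cheap smooth surrogate forward map for optimiser plumbing tests."""
    d = theta.as_dict()
    elv = d["v_a"] * math.exp(-0.3 * d["sigma_v"])
    qp = d["q_p"] * math.exp(-0.1 * d["sigma_p"])
    return ISTMeasurement(elv, 0.9 * elv, qp, 0.95 * qp, settings.dead_space)


class TestOptimizeAndBenchmark:
    @pytest.fixture()
    def fake_forward(self, monkeypatch):
        import istlung.inversion as inv

        monkeypatch.setattr(inv, "run_ist", _fake_run_ist)

    def test_optimize_recovers_surrogate_truth(self, settings, fake_forward):
        truth = ThetaParams(2.3, 4.9)
        measured = _fake_run_ist(truth, settings)
        config = OptimizerConfig(method="nelder_mead", n_iterations=300, seed=0)
        res = optimize(measured, settings, config)
        assert res.loss_star < 0.05
        assert np.all(np.diff(res.loss_trace) <= 0)

    def test_all_failures_yield_failure_result(self, settings, healthy_measurement,
                                               monkeypatch):
        import istlung.inversion as inv

        def boom(*a, **k):
            raise ForwardModelError("always fails")

        monkeypatch.setattr(inv, "run_ist", boom)
        config = OptimizerConfig(method="random", n_iterations=10, seed=0)
        res = optimize(healthy_measurement, settings, config)
        assert res.success is False
        assert math.isinf(res.loss_star)

    def test_benchmark_rows_and_determinism(self, settings, fake_forward):
        measured = _fake_run_ist(ThetaParams(2.3, 4.9), settings)
        configs = [
            OptimizerConfig(method="random", n_iterations=40, seed=3),
            OptimizerConfig(method="random", n_iterations=40, seed=3),
            OptimizerConfig(method="nelder_mead", n_iterations=40, seed=3),
        ]
        bench = benchmark_optimizers(measured, settings, configs)
        assert len(bench.summary) == 3
        first, second = bench.summary.iloc[0], bench.summary.iloc[1]
        assert first["final_loss"] == second["final_loss"]
        table = bench.trace_table()
        # repeated methods get disambiguated labels but identical traces
        assert set(table.columns) == {"random", "random#2", "nelder_mead"}
        assert table["random"].equals(table["random#2"])
        for method in table.columns:
            tr = table[method].dropna().to_numpy()
            assert np.all(np.diff(tr) <= 0)

    def test_benchmark_needs_two_configs(self, settings, fake_forward):
        measured = _fake_run_ist(ThetaParams(2.3, 4.9), settings)
        with pytest.raises(ConfigurationError):
            benchmark_optimizers(
                measured, settings,
                [OptimizerConfig(method="random", n_iterations=5)],
            )


class TestConfigValidation:
    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            OptimizerConfig(method="simulated_annealing")

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            bounds_array({"v_a": (3.0, 1.0)})

    def test_vector_round_trip(self):
        theta = ThetaParams(2.3, 4.9)
        from istlung.inversion import theta_to_vector

        vec = theta_to_vector(theta)
        assert vector_to_theta(vec).as_dict() == theta.as_dict()
        assert [*theta.as_dict()] == list(PARAM_NAMES)
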