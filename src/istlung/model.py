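"""Model/Results interface for the IST heterogeneity inversion.

``LungHeterogeneityModel`` is constructed from the data — an
:class:`~istlung.recovery.ISTMeasurement` and the ventilator settings of the
record — and ``fit()`` runs the simulation-based optimisation, returning a
``LungHeterogeneityResults`` object that carries the recovered parameters,
the loss trace, a repeatability spread when the fit is replicated over seeds,
and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .inversion import (
    OptimizerConfig,
    OptimizationResult,
    PARAM_NAMES,
    bounds_array,
    loss as inversion_loss,
    optimize,
)
from .recovery import ISTMeasurement, run_ist
from .simulator import ThetaParams, VentilatorSettings, discretize_lognormal

__all__ = ["LungHeterogeneityModel", "LungHeterogeneityResults"]


class LungHeterogeneityModel:
    """Simulation-based optimisation model for one IST record.

    Parameters
    ----------
    measurement : ISTMeasurement
        The four observables (ELV, Qp at 180 s and 60 s) plus dead space.
    settings : VentilatorSettings, optional
        Breathing pattern of the record.  Defaults to standard adult settings
        with the dead space replaced by the measured value.
    bounds : dict, optional
        Per-parameter (low, high) overrides of the default search box.

    Examples
    --------
    >>> from istlung import patients
    >>> meas = patients.generate_measurement(patients.preset("healthy").theta)
    >>> model = LungHeterogeneityModel(meas)
    >>> res = model.fit(method="bayes", n_iterations=60, seed=1)
    >>> print(res.summary())                        # doctest: +SKIP
    """

    def __init__(
        self,
        measurement: ISTMeasurement,
        settings: VentilatorSettings | None = None,
        bounds: dict | None = None,
        n_alv: int = 125,
        n_ds: int = 10,
    ):
        if settings is None:
            settings = VentilatorSettings(dead_space=measurement.dead_space)
        elif abs(settings.dead_space - measurement.dead_space) > 1e-9:
            settings = VentilatorSettings(
                tidal_volume=settings.tidal_volume,
                respiratory_rate=settings.respiratory_rate,
                ie_ratio=settings.ie_ratio,
                dead_space=measurement.dead_space,
            )
        self.measurement = measurement
        self.settings = settings
        self.bounds = bounds_array(bounds)
        self.n_alv = n_alv
        self.n_ds = n_ds

    @classmethod
    def from_record(cls, record, **kwargs) -> "LungHeterogeneityModel":
        """Build from a flat mapping/Series with keys elv_180_L, ..., vd_L."""
        if isinstance(record, pd.Series):
            record = record.to_dict()
        return cls(ISTMeasurement.from_dict(record), **kwargs)

    def loss(self, theta: ThetaParams) -> float:
        """Inversion loss of a candidate parameter set against the data."""
        return inversion_loss(
            theta, self.measurement, self.settings,
            n_alv=self.n_alv, n_ds=self.n_ds,
        )

    def fit(
        self,
        method: str = "bayes",
        n_iterations: int | None = None,
        seed: int = 0,
        n_repeats: int = 1,
        **config_kwargs,
    ) -> "LungHeterogeneityResults":
        """Run the inversion; ``n_repeats > 1`` replicates it over consecutive
        seeds and reports the best run plus the across-seed spread."""
        if n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        bounds_dict = {n: tuple(b) for n, b in zip(PARAM_NAMES, self.bounds)}
        runs = []
        for k in range(n_repeats):
            config = OptimizerConfig(
                method=method,
                bounds=bounds_dict,
                n_iterations=n_iterations,
                seed=seed + k,
                **config_kwargs,
            )
            runs.append(
                optimize(
                    self.measurement, self.settings, config,
                    n_alv=self.n_alv, n_ds=self.n_ds,
                )
            )
        best = min(runs, key=lambda r: r.loss_star)
        return LungHeterogeneityResults(self, best, runs)


class LungHeterogeneityResults:
    """Estimates and diagnostics from a fitted :class:`LungHeterogeneityModel`."""

    def __init__(self, model, best: OptimizationResult, runs):
        self.model = model
        self._best = best
        self.runs = list(runs)
        self.theta = best.theta_star
        self.params = pd.Series(best.theta_star.as_dict())
        self.loss = best.loss_star
        self.loss_trace = best.loss_trace
        self.n_evaluations = best.n_evaluations
        self.success = best.success
        self.seed = best.seed
        self.method = best.method

    @property
    def spread(self) -> pd.Series | None:
        """Across-repeat relative spread 100*(max-min)/mean per parameter (%)."""
        if len(self.runs) < 2:
            return None
        mat = np.array([[r.theta_star.as_dict()[n] for n in PARAM_NAMES] for r in self.runs])
        spread = 100.0 * (mat.max(axis=0) - mat.min(axis=0)) / mat.mean(axis=0)
        return pd.Series(spread, index=PARAM_NAMES)

    def predicted(self) -> ISTMeasurement:
        """IST observables of the fitted lung (forward map at theta*)."""
        return run_ist(
            self.theta, self.model.settings,
            n_alv=self.model.n_alv, n_ds=self.model.n_ds,
        )

    def summary(self) -> str:
        meas = self.model.measurement
        pred = self.predicted()
        lines = [
            "IST lung-heterogeneity inversion",
            "=" * 48,
            f"method: {self.method}    seed: {self.seed}"
            f"    evaluations: {self.n_evaluations}",
            f"final loss: {self.loss:.6f}    success: {self.success}",
            "-" * 48,
            f"{'parameter':<10}{'estimate':>12}{'low':>9}{'high':>9}",
        ]
        for name, (lo, hi) in zip(PARAM_NAMES, self.model.bounds):
            lines.append(f"{name:<10}{self.params[name]:>12.4f}{lo:>9.2f}{hi:>9.2f}")
        sp = self.spread
        if sp is not None:
            lines.append("-" * 48)
            lines.append(f"repeatability over {len(self.runs)} seeds, 100*(max-min)/mean:")
            for name in PARAM_NAMES:
                lines.append(f"  {name:<10}{sp[name]:>8.2f} %")
        lines.append("-" * 48)
        lines.append(f"{'observable':<12}{'measured':>11}{'fitted':>11}")
        for attr in ("elv_180", "elv_60", "qp_180", "qp_60"):
            lines.append(
                f"{attr:<12}{getattr(meas, attr):>11.4f}{getattr(pred, attr):>11.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "theta": self.theta.as_dict(),
            "loss": self.loss,
            "success": self.success,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "method": self.method,
        }
        if self.spread is not None:
            d["spread_percent"] = self.spread.to_dict()
        return d

    def plot_trace(self, ax=None):
        """Best-loss-so-far versus evaluation index."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for r in self.runs:
            ax.plot(r.loss_trace, alpha=0.8, label=f"seed {r.seed}")
        ax.set_xlabel("evaluation")
        ax.set_ylabel("best loss")
        ax.set_yscale("log")
        if len(self.runs) > 1:
            ax.legend()
        return ax

    def plot_distributions(self, ax=None, n: int = 125):
        """Recovered lognormal ventilation/perfusion weight profiles."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for spec, label in ((self.theta.vent, "ventilation"), (self.theta.perf, "perfusion")):
            ax.plot(np.sort(discretize_lognormal(spec, n))[::-1], label=f"{label} (sigma={spec.sigma:.2f})")
        ax.set_xlabel("compartment (sorted)")
        ax.set_ylabel("fraction")
        ax.legend()
        return ax
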