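"""Inverting IST observables into lung-heterogeneity parameters.

The loss is the sum of the absolute relative mismatches of the four IST
observables (ELV and Qp at the 180 s and 60 s forcing periods) between the
simulated lung at candidate parameters ``theta`` and the measured record:

    f(theta) = |dELV_180|/ELV_180^M + |dELV_60|/ELV_60^M
             + |dQp_180|/Qp_180^M  + |dQp_60|/Qp_60^M

Three derivative-free minimisers over a bounded box are provided: Bayesian
optimisation (Gaussian-process surrogate, Matérn-5/2 kernel, expected
improvement acquisition, Latin-hypercube initial design), bounded Nelder–Mead
with restarts, and uniform random search.  All are deterministic given a seed.

Note that with fractions obtained by normalising the lognormal weights, the
location parameters mu_V and mu_P cancel exactly and the loss is flat along
those two axes; only (V_A, Q_P, sigma_V, sigma_P) are identifiable from the
four observables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, minimize
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .exceptions import ConfigurationError, ForwardModelError, UndefinedInputError
from .recovery import ISTMeasurement, run_ist
from .simulator import ThetaParams, VentilatorSettings

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_BOUNDS",
    "OptimizerConfig",
    "OptimizationResult",
    "BenchmarkResult",
    "observable_mismatch_loss",
    "loss",
    "minimize_objective",
    "optimize",
    "success_rate",
    "benchmark_optimizers",
]

#: Order of the six theta components in vector form.
PARAM_NAMES = ("v_a", "q_p", "mu_v", "sigma_v", "mu_p", "sigma_p")

#: Default search box.  V_A in litres, Q_P in L/min, mu/sigma dimensionless.
DEFAULT_BOUNDS = {
    "v_a": (0.2, 6.0),
    "q_p": (0.5, 10.0),
    "mu_v": (0.5, 2.0),
    "sigma_v": (0.01, 2.0),
    "mu_p": (0.5, 2.0),
    "sigma_p": (0.01, 2.0),
}

#: Default evaluation budgets per method (test profile uses 60/120/120).
DEFAULT_BUDGETS = {"bayes": 200, "nelder_mead": 400, "random": 400}


def theta_to_vector(theta: ThetaParams) -> np.ndarray:
    d = theta.as_dict()
    return np.array([d[name] for name in PARAM_NAMES])


def vector_to_theta(x) -> ThetaParams:
    return ThetaParams.from_dict(dict(zip(PARAM_NAMES, np.asarray(x, float))))


def bounds_array(bounds: dict | None = None) -> np.ndarray:
    """(6, 2) array of (low, high) rows in PARAM_NAMES order."""
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    arr = np.array([merged[name] for name in PARAM_NAMES], dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr[:, 0] >= arr[:, 1]):
        raise ConfigurationError("bounds must be finite with low < high")
    return arr


@dataclass(frozen=True)
class OptimizerConfig:
    """Configuration of one inversion run."""

    method: str = "bayes"
    bounds: dict | None = None
    n_iterations: int | None = None
    seed: int = 0
    success_loss_threshold: float = 0.05
    n_restarts: int = 3
    n_initial: int = 10
    mu_penalty_weight: float = 0.0

    def __post_init__(self):
        if self.method not in ("bayes", "nelder_mead", "random"):
            raise ConfigurationError(
                f"unknown method {self.method!r}; choose bayes|nelder_mead|random"
            )
        if self.n_iterations is not None and self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")

    @property
    def budget(self) -> int:
        return self.n_iterations or DEFAULT_BUDGETS[self.method]


@dataclass
class OptimizationResult:
    """Outcome of one inversion: best parameters, loss and trace."""

    theta_star: ThetaParams
    loss_star: float
    loss_trace: np.ndarray
    n_evaluations: int
    success: bool
    seed: int
    method: str

    def params(self) -> pd.Series:
        return pd.Series(self.theta_star.as_dict())


# --------------------------------------------------------------------------
# Loss
# --------------------------------------------------------------------------

def observable_mismatch_loss(simulated: ISTMeasurement, measured: ISTMeasurement) -> float:
    """Sum of absolute relative observable mismatches (dimensionless)."""
    sim = simulated.observables
    meas = measured.observables
    return float(np.sum(np.abs((sim - meas) / meas)))


def loss(
    theta: ThetaParams,
    measured: ISTMeasurement,
    settings: VentilatorSettings,
    **run_ist_kwargs,
) -> float:
    """Inversion loss at ``theta``; +inf if the forward map fails."""
    if np.any(measured.observables <= 0):
        raise ConfigurationError("measured observables must all be > 0")
    try:
        sim = run_ist(theta, settings, **run_ist_kwargs)
    except (ForwardModelError, ConfigurationError):
        return math.inf
    return observable_mismatch_loss(sim, measured)


# --------------------------------------------------------------------------
# Generic bounded minimisation of a scalar objective
# --------------------------------------------------------------------------

class _TrackedObjective:
    """Wraps the objective in [0,1]^d coordinates with caching and a trace.

    ``fn`` may return either a scalar loss or a vector of signed residuals
    whose absolute values sum to the loss; residual vectors are kept so the
    Bayesian optimiser can build per-observable surrogates.
    """

    def __init__(self, fn, box: np.ndarray, budget: int):
        self.fn = fn
        self.lo = box[:, 0]
        self.span = box[:, 1] - box[:, 0]
        self.budget = budget
        self.X: list[np.ndarray] = []
        self.y: list[float] = []
        self.R: list[np.ndarray | None] = []
        self.trace: list[float] = []
        self._cache: dict = {}

    def to_physical(self, z):
        return self.lo + np.asarray(z) * self.span

    def exhausted(self) -> bool:
        return len(self.y) >= self.budget

    def _key(self, z):
        return tuple(np.round(z * self.span + self.lo, 6))

    def is_cached(self, z) -> bool:
        z = np.clip(np.asarray(z, float), 0.0, 1.0)
        return self._key(z) in self._cache

    def residual_at(self, z):
        """Residual vector of an already-evaluated point (None if scalar)."""
        z = np.clip(np.asarray(z, float), 0.0, 1.0)
        return self._cache.get(self._key(z), (None, None))[1]

    def __call__(self, z) -> float:
        z = np.clip(np.asarray(z, float), 0.0, 1.0)
        key = self._key(z)
        if key in self._cache:
            return self._cache[key][0]
        if self.exhausted():
            raise _BudgetExhausted
        out = self.fn(self.to_physical(z))
        if np.ndim(out) == 0:
            val, resid = float(out), None
        else:
            resid = np.asarray(out, float)
            val = float(np.sum(np.abs(resid)))
            if not np.all(np.isfinite(resid)):
                val, resid = math.inf, None
        self._cache[key] = (val, resid)
        self.X.append(z)
        self.y.append(val)
        self.R.append(resid)
        best = min(val, self.trace[-1]) if self.trace else val
        self.trace.append(best)
        return val

    @property
    def best(self):
        finite = [(v, i) for i, v in enumerate(self.y) if math.isfinite(v)]
        if not finite:
            return None, math.inf
        v, i = min(finite)
        return self.X[i], v


class _BudgetExhausted(Exception):
    pass


def _expected_improvement(mu, sigma, y_best):
    sigma = np.maximum(sigma, 1e-12)
    imp = y_best - mu
    z = imp / sigma
    return imp * norm.cdf(z) + sigma * norm.pdf(z)


def _folded_moments(mu, sigma):
    """Mean and variance of |X| for X ~ N(mu, sigma) (elementwise)."""
    sigma = np.maximum(sigma, 1e-12)
    z = mu / sigma
    mean = mu * (1.0 - 2.0 * norm.cdf(-z)) + sigma * np.sqrt(2.0 / np.pi) * np.exp(
        -0.5 * z**2
    )
    var = np.maximum(mu**2 + sigma**2 - mean**2, 1e-18)
    return mean, var


def _make_gp(d, seed):
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=np.full(d, 0.2),
        length_scale_bounds=(0.03, 30.0),
        nu=2.5,
    )
    return GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-10,
        normalize_y=True,
        n_restarts_optimizer=1,
        random_state=seed,
    )


def _fit_surrogate(obj: _TrackedObjective, d: int, rng):
    """Fit the surrogate to all evaluations so far; return a predictor.

    When the objective exposes its signed residual vector, one GP is fitted
    per residual (the residuals are smooth where the summed absolute loss is
    kinked) and the loss posterior is reassembled from folded-normal moments;
    otherwise a single GP models the log-warped scalar loss.
    """
    X = np.array(obj.X)
    y_arr = np.array(obj.y)
    have_resid = [r is not None for r in obj.R]
    if sum(have_resid) >= max(d + 2, 5):
        keep = np.flatnonzero(have_resid)
        R = np.array([obj.R[i] for i in keep])
        Xm = X[keep]
        gps = []
        for k in range(R.shape[1]):
            gp = _make_gp(d, int(rng.integers(2**31)))
            gp.fit(Xm, R[:, k])
            gps.append(gp)

        def predict(Z):
            Z = np.atleast_2d(Z)
            mean = np.zeros(len(Z))
            var = np.zeros(len(Z))
            for gp in gps:
                mu_k, sd_k = gp.predict(Z, return_std=True)
                m_k, v_k = _folded_moments(mu_k, sd_k)
                mean += m_k
                var += v_k
            return mean, np.sqrt(var)

        def plugin_loss(Z):
            # Gauss-Newton style plug-in: loss at the signed GP means.
            # Unlike the folded mean it is not penalised by predictive sd,
            # so its minimiser extrapolates to the surrogate's root instead
            # of sticking to already-sampled points.
            Z = np.atleast_2d(Z)
            total = np.zeros(len(Z))
            for gp in gps:
                total += np.abs(gp.predict(Z))
            return total

        return predict, plugin_loss

    else:
        big = 1e3  # stand-in for +inf forward failures
        y = np.log(np.minimum(y_arr, big) + 1e-4)
        gp = _make_gp(d, int(rng.integers(2**31)))
        gp.fit(X, y)

        def predict(Z):
            return gp.predict(np.atleast_2d(Z), return_std=True)

        def plugin_loss(Z):
            return predict(Z)[0]

    return predict, plugin_loss


def _surrogate_minimum(plugin_loss, starts, bounds_lo, bounds_hi):
    """Multi-start L-BFGS minimisation of the plug-in surrogate loss."""
    best_z, best_m = None, math.inf
    for z0 in starts:
        res = minimize(
            lambda z: float(plugin_loss(np.clip(z, bounds_lo, bounds_hi))[0]),
            np.clip(z0, bounds_lo, bounds_hi),
            method="L-BFGS-B",
            bounds=Bounds(bounds_lo, bounds_hi),
            options={"maxfun": 30},
        )
        if res.fun < best_m:
            best_z, best_m = np.clip(res.x, bounds_lo, bounds_hi), float(res.fun)
    return best_z, best_m


def _evaluate_novel(obj, z_next, fallback, rng, d):
    """Evaluate z_next, falling back to the best novel candidate if cached."""
    if obj.is_cached(z_next):
        for z in fallback:
            if not obj.is_cached(z):
                z_next = z
                break
        else:
            z_next = rng.uniform(size=d)
    return obj(z_next)


def _run_bayes(obj: _TrackedObjective, d: int, config: OptimizerConfig):
    """Bayesian optimisation: EI exploration, then trust-region descent.

    Phase 1 (60% of the budget after the Latin-hypercube design) maximises
    expected improvement of the surrogate loss posterior over mixed
    global/local candidates, refined by an L-BFGS polish and multi-start
    surrogate-mean "believer" candidates. Phase 2 spends the remaining
    budget on an adaptive trust region around the incumbent, proposing the
    surrogate-mean minimiser within the region and expanding or shrinking
    the region on success or failure -- this descends the weakly-determined
    ridges of the loss far faster than EI once the basin is located.
    """
    rng = np.random.default_rng(config.seed)
    n_init = min(config.n_initial, obj.budget)
    sampler = qmc.LatinHypercube(d=d, seed=int(rng.integers(2**31)))
    for z in sampler.random(n_init):
        obj(z)

    zeros, ones = np.zeros(d), np.ones(d)

    # ---- phase 1: expected improvement ------------------------------------
    while len(obj.y) < int(0.3 * obj.budget) and not obj.exhausted():
        predict, plugin_loss = _fit_surrogate(obj, d, rng)
        y_arr = np.array(obj.y)
        z_best, loss_best = obj.best
        if z_best is None:
            z_best, loss_best = np.array(obj.X)[int(np.argmin(y_arr))], 1.0
        y_incumbent = float(np.min(y_arr[np.isfinite(y_arr)]))
        r = float(np.clip(loss_best if math.isfinite(loss_best) else 1.0,
                          0.002, 0.1))
        cand = np.vstack([
            rng.uniform(size=(512, d)),
            np.clip(z_best + 0.1 * rng.standard_normal((96, d)), 0, 1),
            np.clip(z_best + 3 * r * rng.standard_normal((64, d)), 0, 1),
            np.clip(z_best + r * rng.standard_normal((64, d)), 0, 1),
        ])
        finite_idx = np.flatnonzero(np.isfinite(y_arr))
        top = finite_idx[np.argsort(y_arr[finite_idx])[:2]]
        believer, _ = _surrogate_minimum(
            plugin_loss,
            [z_best, *np.array(obj.X)[top], *rng.uniform(size=(3, d))],
            zeros, ones,
        )
        if believer is not None:
            cand = np.vstack([cand, believer])

        mu, sigma = predict(cand)
        ei = _expected_improvement(mu, sigma, y_incumbent)
        z_next = cand[int(np.argmax(ei))]

        def neg_ei(z):
            m, s = predict(np.clip(z, 0, 1))
            return -float(_expected_improvement(m, s, y_incumbent)[0])

        polish = minimize(
            neg_ei, z_next, method="L-BFGS-B",
            bounds=Bounds(zeros, ones), options={"maxfun": 40},
        )
        if polish.fun < -float(np.max(ei)):
            z_next = np.clip(polish.x, 0, 1)
        _evaluate_novel(obj, z_next, cand[np.argsort(-ei)], rng, d)

    # ---- phase 2: local refinement ----------------------------------------
    if any(r is not None for r in obj.R):
        _gauss_newton_refine(obj, d, rng)
    else:
        _trust_region_descent(obj, d, rng)


def _incumbent_with_residuals(obj):
    idx = [
        i for i, (v, r) in enumerate(zip(obj.y, obj.R))
        if r is not None and math.isfinite(v)
    ]
    if not idx:
        return None, None, math.inf
    i = min(idx, key=lambda j: obj.y[j])
    return obj.X[i], np.asarray(obj.R[i]), obj.y[i]


def _gauss_newton_refine(obj: _TrackedObjective, d: int, rng):
    """Damped Gauss-Newton on the true residual vector, with basin restarts.

    Each descent spends up to d evaluations on a forward-difference Jacobian
    and up to three on Levenberg-Marquardt trial steps; convergence is
    quadratic on the smooth least-squares structure of the observable
    residuals, far below what the surrogate alone resolves.  The loss has a
    secondary local minimum (a compensation solution with inflated
    sigma_V/sigma_P), so when a descent stalls at a high floor the
    refinement restarts — first from the surrogate's global plug-in
    minimiser away from the basins already visited, falling back to the
    best evaluated point away from them.
    """
    excluded: list[np.ndarray] = []
    flat_hint = None
    try:
        while not obj.exhausted() and len(excluded) < 4:
            if not excluded:
                start = _pick_start(obj, excluded)
            else:
                start = _surrogate_restart(obj, d, rng, excluded)
                if start is None:
                    start = _pick_start(obj, excluded)
            if start is None:
                break
            z_end, y_end, J_last = _gn_descend(obj, start, d, rng,
                                               flat_hint=flat_hint)
            if J_last is not None:
                col = np.linalg.norm(J_last, axis=0)
                flat_hint = col < 1e-3 * max(col.max(), 1e-12)
            excluded.append(z_end)
            if y_end < 5e-4:
                break
    except _BudgetExhausted:
        pass


def _pick_start(obj: _TrackedObjective, excluded, min_dist: float = 0.2):
    """Best evaluated point with residuals, away from descended basins."""
    order = sorted(
        (
            i for i, (v, r) in enumerate(zip(obj.y, obj.R))
            if r is not None and math.isfinite(v)
        ),
        key=lambda j: obj.y[j],
    )
    for i in order:
        z = obj.X[i]
        if all(np.linalg.norm(z - e) >= min_dist for e in excluded):
            return z
    return None


def _surrogate_restart(obj, d, rng, excluded, min_dist: float = 0.2):
    """Global plug-in surrogate minimiser outside the visited basins."""
    _, plugin_loss = _fit_surrogate(obj, d, rng)
    solutions = []
    starts = [*rng.uniform(size=(6, d))]
    far = _pick_start(obj, excluded, min_dist)
    if far is not None:
        starts.append(far)
    for z0 in starts:
        res = minimize(
            lambda z: float(plugin_loss(np.clip(z, 0, 1))[0]),
            z0, method="L-BFGS-B",
            bounds=Bounds(np.zeros(d), np.ones(d)),
            options={"maxfun": 30},
        )
        solutions.append((float(res.fun), np.clip(res.x, 0, 1)))
    for _, z in sorted(solutions, key=lambda t: t[0]):
        if all(np.linalg.norm(z - e) >= min_dist for e in excluded):
            return z
    return None


def _gn_descend(obj: _TrackedObjective, z0, d: int, rng, flat_hint=None):
    """One Levenberg-Marquardt descent; returns (end point, loss, Jacobian).

    Finite-difference columns are re-used for dimensions whose previous
    Jacobian column was negligible (the loss is exactly flat along the two
    lognormal location axes, so probing them every iteration wastes
    evaluations); flat dimensions are re-probed every third iteration.
    ``flat_hint`` seeds that mask from an earlier descent.
    """
    lam = 1e-2
    z_cur = np.asarray(z0, float)
    obj(z_cur)
    r_cur = obj.residual_at(z_cur)
    if r_cur is None:
        return z_cur, math.inf, None
    y_cur = float(np.sum(np.abs(r_cur)))
    J_prev = None
    iteration = 0
    h = 0.004  # finite-difference step in unit-box coordinates
    while not obj.exhausted() and y_cur > 1e-9:
        K = len(r_cur)
        J = np.zeros((K, d))
        if J_prev is not None and iteration % 3 != 0:
            col_norm = np.linalg.norm(J_prev, axis=0)
            flat = col_norm < 1e-3 * max(col_norm.max(), 1e-12)
        elif J_prev is None and flat_hint is not None and iteration == 0:
            flat = np.asarray(flat_hint, bool)
            J_prev = np.zeros((K, d))
        else:
            flat = np.zeros(d, dtype=bool)
        valid = True
        for i in range(d):
            if flat[i]:
                J[:, i] = J_prev[:, i]
                continue
            step = h if z_cur[i] + h <= 1.0 else -h
            zi = z_cur.copy()
            zi[i] += step
            obj(zi)
            ri = obj.residual_at(zi)
            if ri is None:
                valid = False
                break
            J[:, i] = (ri - r_cur) / step
        if not valid:
            break
        J_prev = J
        iteration += 1
        improved = False
        for _ in range(3):
            if obj.exhausted():
                raise _BudgetExhausted
            delta = np.linalg.solve(J.T @ J + lam * np.eye(d), -J.T @ r_cur)
            z_new = np.clip(z_cur + delta, 0, 1)
            if obj.is_cached(z_new):
                z_new = np.clip(z_new + 1e-4 * rng.standard_normal(d), 0, 1)
            y_new = obj(z_new)
            r_new = obj.residual_at(z_new)
            if y_new < y_cur and r_new is not None:
                z_cur, r_cur, y_cur = z_new, r_new, y_new
                lam = max(lam / 3.0, 1e-5)
                improved = True
                break
            lam *= 10.0
        if not improved:
            break  # basin floor reached; let the caller restart elsewhere
    return z_cur, y_cur, J_prev


def _trust_region_descent(obj: _TrackedObjective, d: int, rng):
    """Adaptive trust-region descent on the surrogate (scalar objectives)."""
    tr = 0.12
    fails = 0
    while not obj.exhausted():
        predict, plugin_loss = _fit_surrogate(obj, d, rng)
        z_best, loss_best = obj.best
        if z_best is None:
            break
        lo = np.clip(z_best - tr, 0, 1)
        hi = np.clip(z_best + tr, 0, 1)
        cand = lo + (hi - lo) * rng.uniform(size=(128, d))
        believer, _ = _surrogate_minimum(
            plugin_loss, [z_best, *(lo + (hi - lo) * rng.uniform(size=(3, d)))],
            lo, hi,
        )
        if believer is not None:
            cand = np.vstack([cand, believer])
        score = plugin_loss(cand)
        order = np.argsort(score)
        y_new = _evaluate_novel(obj, cand[order[0]], cand[order[1:]], rng, d)
        if y_new < loss_best - 1e-12:
            tr = min(0.3, tr * 1.4)
            fails = 0
        else:
            fails += 1
            if fails >= 2:
                tr = max(0.003, tr / 2.0)
                fails = 0


def _run_nelder_mead(obj: _TrackedObjective, d: int, config: OptimizerConfig):
    rng = np.random.default_rng(config.seed)
    n_rest = max(1, config.n_restarts)
    per_restart = max(d + 2, obj.budget // n_rest)
    starts = [np.full(d, 0.5)] + [rng.uniform(size=d) for _ in range(n_rest - 1)]

    def penalised(z):
        # +inf breaks the simplex update; use a large finite sentinel instead
        v = obj(z)
        return v if math.isfinite(v) else 1e6

    for z0 in starts:
        if obj.exhausted():
            break
        try:
            minimize(
                penalised,
                z0,
                method="Nelder-Mead",
                bounds=Bounds(np.zeros(d), np.ones(d)),
                options={
                    "maxfev": min(per_restart, obj.budget - len(obj.y)),
                    "xatol": 1e-6,
                    "fatol": 1e-9,
                    "adaptive": True,
                },
            )
        except _BudgetExhausted:
            break


def _run_random(obj: _TrackedObjective, d: int, config: OptimizerConfig):
    rng = np.random.default_rng(config.seed)
    while not obj.exhausted():
        obj(rng.uniform(size=d))


def minimize_objective(fn, box: np.ndarray, config: OptimizerConfig):
    """Minimise ``fn`` (physical coordinates) over box with the chosen method.

    Returns ``(x_best, y_best, trace, n_evaluations)``; ``x_best`` is None if
    every evaluation failed (+inf).
    """
    box = np.asarray(box, float)
    d = box.shape[0]
    obj = _TrackedObjective(fn, box, config.budget)
    runner = {
        "bayes": _run_bayes,
        "nelder_mead": _run_nelder_mead,
        "random": _run_random,
    }[config.method]
    try:
        runner(obj, d, config)
    except _BudgetExhausted:
        pass
    z_best, y_best = obj.best
    x_best = None if z_best is None else obj.to_physical(z_best)
    return x_best, y_best, np.asarray(obj.trace), len(obj.y)


# --------------------------------------------------------------------------
# IST inversion entry points
# --------------------------------------------------------------------------

def optimize(
    measured: ISTMeasurement,
    settings: VentilatorSettings,
    config: OptimizerConfig | None = None,
    **run_ist_kwargs,
) -> OptimizationResult:
    """Invert an IST measurement into lung parameters.

    ``success`` requires the final loss to be below the configured threshold
    *and* the recovered parameters to sit strictly inside the search box
    (solutions pinned at a bound are treated as non-meaningful).
    """
    config = config or OptimizerConfig()
    box = bounds_array(config.bounds)
    w = config.mu_penalty_weight
    mu_idx = [PARAM_NAMES.index("mu_v"), PARAM_NAMES.index("mu_p")]
    meas_obs = measured.observables
    if np.any(meas_obs <= 0):
        raise ConfigurationError("measured observables must all be > 0")

    def objective(x):
        """Signed relative residual vector; sum of |.| is the loss."""
        try:
            sim = run_ist(vector_to_theta(x), settings, **run_ist_kwargs)
        except (ForwardModelError, ConfigurationError):
            return math.inf
        resid = (sim.observables - meas_obs) / meas_obs
        if w > 0:
            resid = np.concatenate([resid, w * (x[mu_idx] - 1.0) ** 2])
        return resid

    x_best, y_best, trace, n_eval = minimize_objective(objective, box, config)
    if x_best is None:
        centre = box.mean(axis=1)
        return OptimizationResult(
            theta_star=vector_to_theta(centre),
            loss_star=math.inf,
            loss_trace=trace,
            n_evaluations=n_eval,
            success=False,
            seed=config.seed,
            method=config.method,
        )
    interior = bool(np.all(x_best > box[:, 0]) and np.all(x_best < box[:, 1]))
    return OptimizationResult(
        theta_star=vector_to_theta(x_best),
        loss_star=y_best,
        loss_trace=trace,
        n_evaluations=n_eval,
        success=bool(y_best < config.success_loss_threshold and interior),
        seed=config.seed,
        method=config.method,
    )


def success_rate(results) -> float:
    """Percentage of runs flagged successful."""
    results = list(results)
    if not results:
        raise UndefinedInputError("success_rate of an empty result list is undefined")
    return 100.0 * sum(r.success for r in results) / len(results)


@dataclass
class BenchmarkResult:
    """Aligned optimiser comparison: per-method summary and loss traces."""

    summary: pd.DataFrame
    traces: pd.DataFrame

    def trace_table(self) -> pd.DataFrame:
        """Traces pivoted to evaluation-index rows, one column per method."""
        return self.traces.pivot(index="evaluation", columns="method", values="best_loss")


def benchmark_optimizers(
    measured: ISTMeasurement,
    settings: VentilatorSettings,
    configs,
    **run_ist_kwargs,
) -> BenchmarkResult:
    """Run several optimiser configurations on the same measured record."""
    configs = list(configs)
    if len(configs) < 2:
        raise ConfigurationError("benchmark needs at least 2 optimiser configs")
    rows, trace_rows = [], []
    seen: dict = {}
    for config in configs:
        seen[config.method] = seen.get(config.method, 0) + 1
        label = config.method
        if seen[label] > 1:
            label = f"{label}#{seen[config.method]}"
        try:
            res = optimize(measured, settings, config, **run_ist_kwargs)
            rows.append(
                {
                    "method": label,
                    "final_loss": res.loss_star,
                    "n_evaluations": res.n_evaluations,
                    "success": res.success,
                    "seed": res.seed,
                    "failed": False,
                }
            )
            for i, v in enumerate(res.loss_trace):
                trace_rows.append({"method": label, "evaluation": i, "best_loss": v})
        except Exception as exc:  # a failed method becomes a failed row
            rows.append(
                {
                    "method": label,
                    "final_loss": math.inf,
                    "n_evaluations": 0,
                    "success": False,
                    "seed": config.seed,
                    "failed": True,
                    "error": str(exc),
                }
            )
    return BenchmarkResult(
        summary=pd.DataFrame(rows), traces=pd.DataFrame(trace_rows)
    )
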