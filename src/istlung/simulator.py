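"""Breath-by-breath forward simulation of tracer transport in a heterogeneous lung.

The lung is discretised into ``n_alv`` tidally ventilated alveolar compartments
of equal volume fed through a common series chain of ``n_ds`` well-mixed
dead-space stages, with net tracer uptake recirculating through a small set of
parallel body-tissue compartments.  Ventilation and perfusion are distributed
across the alveolar compartments as normalised fractions derived from lognormal
distributions of specific ventilation and specific perfusion: compartment ``i``
receives weight ``s_i = exp(ln mu + sigma * Phi^-1((i - 0.5)/n))`` (the
equal-probability quantile midpoint of the lognormal), normalised so the
fractions sum to one.  ``sigma`` is the heterogeneity index: ``sigma = 0`` is a
perfectly homogeneous lung, larger values widen the spread of compartmental
time constants.

The model advances one full breath per step (inspiration, gas exchange,
expiration, venous update) and is exactly tracer-conserving by construction:
per breath, inspired minus expired tracer minus net blood uptake equals the
change of tracer stored in the lung, to floating-point precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .exceptions import (
    ConfigurationError,
    UnphysicalDistributionError,
    UnphysicalForcingError,
)

__all__ = [
    "LognormalSpec",
    "ThetaParams",
    "VentilatorSettings",
    "SinewaveForcing",
    "CompartmentalLung",
    "BodyCompartmentSet",
    "BreathSeries",
    "discretize_lognormal",
    "build_lung",
    "default_body",
    "simulate",
]

#: Blood-gas partition coefficient of nitrous oxide (dimensionless).
N2O_BLOOD_GAS_PARTITION = 0.47


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal distribution of a specific (per-unit-volume) rate.

    Parameters
    ----------
    mu : float
        Ratio-scale median of the distribution, > 0.  Close to 1 in health.
    sigma : float
        Log standard deviation, >= 0.  ``sigma = 0`` degenerates to a point
        distribution at ``mu``; larger values mean a more heterogeneous lung.
    """

    mu: float = 1.0
    sigma: float = 0.0

    def __post_init__(self):
        if not (self.mu > 0):
            raise ConfigurationError(f"lognormal mu must be > 0, got {self.mu}")
        if self.sigma < 0:
            raise ConfigurationError(
                f"lognormal sigma must be >= 0, got {self.sigma}"
            )


@dataclass(frozen=True)
class ThetaParams:
    """The six-dimensional unknown of the inverse problem.

    ``(V_A, Q_P, mu_V, sigma_V, mu_P, sigma_P)``: total alveolar volume (L),
    pulmonary blood flow (L/min), and the lognormal location/width parameters
    of the ventilation and perfusion distributions.
    """

    v_a: float
    q_p: float
    vent: LognormalSpec = field(default_factory=LognormalSpec)
    perf: LognormalSpec = field(default_factory=LognormalSpec)

    def __post_init__(self):
        if not (self.v_a > 0):
            raise ConfigurationError(f"V_A must be > 0, got {self.v_a}")
        if self.q_p < 0:
            raise ConfigurationError(f"Q_P must be >= 0, got {self.q_p}")

    def as_dict(self) -> dict:
        return {
            "v_a": self.v_a,
            "q_p": self.q_p,
            "mu_v": self.vent.mu,
            "sigma_v": self.vent.sigma,
            "mu_p": self.perf.mu,
            "sigma_p": self.perf.sigma,
        }

    @classmethod
    def from_dict(cls, d) -> "ThetaParams":
        return cls(
            v_a=float(d["v_a"]),
            q_p=float(d["q_p"]),
            vent=LognormalSpec(float(d.get("mu_v", 1.0)), float(d.get("sigma_v", 0.0))),
            perf=LognormalSpec(float(d.get("mu_p", 1.0)), float(d.get("sigma_p", 0.0))),
        )


@dataclass(frozen=True)
class VentilatorSettings:
    """Breathing-pattern inputs taken from the subject's record.

    tidal_volume and dead_space in litres, respiratory_rate in breaths/min,
    ie_ratio is the inspiration:expiration time ratio (0.5 means 1:2).
    """

    tidal_volume: float = 0.5
    respiratory_rate: float = 12.0
    ie_ratio: float = 0.5
    dead_space: float = 0.15

    def __post_init__(self):
        if not (self.tidal_volume > self.dead_space > 0):
            raise ConfigurationError(
                "require tidal_volume > dead_space > 0, got "
                f"V_T={self.tidal_volume}, V_D={self.dead_space}"
            )
        if not (self.respiratory_rate > 0):
            raise ConfigurationError(
                f"respiratory_rate must be > 0, got {self.respiratory_rate}"
            )
        if not (self.ie_ratio > 0):
            raise ConfigurationError(f"ie_ratio must be > 0, got {self.ie_ratio}")

    @property
    def breath_duration(self) -> float:
        """Duration of one breath in seconds."""
        return 60.0 / self.respiratory_rate

    @property
    def alveolar_tidal_volume(self) -> float:
        """Effective alveolar ventilation per breath, V_T - V_D (L)."""
        return self.tidal_volume - self.dead_space


@dataclass(frozen=True)
class SinewaveForcing:
    """Sinusoidal modulation of the inspired tracer fraction.

    ``f_insp(t) = mean_fraction + amplitude_fraction * sin(2 pi t / period + phase)``
    """

    period: float
    mean_fraction: float = 0.04
    amplitude_fraction: float = 0.02
    phase: float = 0.0

    def __post_init__(self):
        if not (self.period > 0):
            raise ConfigurationError(f"period must be > 0, got {self.period}")
        if self.amplitude_fraction < 0:
            raise ConfigurationError("amplitude_fraction must be >= 0")
        if self.mean_fraction - self.amplitude_fraction < 0 or (
            self.mean_fraction + self.amplitude_fraction >= 1
        ):
            raise UnphysicalForcingError(
                "forcing must keep inspired fraction within [0, 1): got mean "
                f"{self.mean_fraction}, amplitude {self.amplitude_fraction}"
            )

    def fraction_at(self, t) -> np.ndarray:
        """Inspired fraction at time(s) ``t`` (seconds)."""
        return self.mean_fraction + self.amplitude_fraction * np.sin(
            2.0 * np.pi * np.asarray(t, dtype=float) / self.period + self.phase
        )


# --------------------------------------------------------------------------
# Lognormal discretisation
# --------------------------------------------------------------------------

def discretize_lognormal(spec: LognormalSpec, n: int, total: float = 1.0) -> np.ndarray:
    """Discretise a lognormal into ``n`` normalised nonnegative weights.

    Uses deterministic equal-probability quantile midpoints
    ``s_i = exp(ln mu + sigma * Phi^-1((i - 0.5)/n))`` for ``i = 1..n``,
    normalised to sum to ``total``.  Deterministic, so the forward model and
    the inversion built on it are well-posed.

    Raises
    ------
    UnphysicalDistributionError
        If the weights are non-finite (sigma absurdly large).
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    p = (np.arange(1, n + 1) - 0.5) / n
    s = np.exp(np.log(spec.mu) + spec.sigma * ndtri(p))
    if not np.all(np.isfinite(s)) or s.sum() == 0:
        raise UnphysicalDistributionError(
            f"non-finite lognormal weights for mu={spec.mu}, sigma={spec.sigma}"
        )
    return total * s / s.sum()


# --------------------------------------------------------------------------
# Lung and body state
# --------------------------------------------------------------------------

@dataclass
class CompartmentalLung:
    """Discretised lung: serial dead-space stages feeding parallel alveoli."""

    alveolar_volumes: np.ndarray
    vent_fractions: np.ndarray
    perf_fractions: np.ndarray
    deadspace_volumes: np.ndarray
    alveolar_concentrations: np.ndarray

    @property
    def n_alveolar(self) -> int:
        return len(self.alveolar_volumes)

    @property
    def n_deadspace(self) -> int:
        return len(self.deadspace_volumes)

    def validate(self):
        for name, frac in (("vent", self.vent_fractions), ("perf", self.perf_fractions)):
            if abs(frac.sum() - 1.0) > 1e-12:
                raise ConfigurationError(f"{name} fractions must sum to 1")
            if np.any(frac < 0):
                raise ConfigurationError(f"{name} fractions must be >= 0")


@dataclass
class BodyCompartmentSet:
    """Parallel body-tissue compartments receiving the tracer taken up by blood.

    Defaults are textbook tissue groups: vessel-rich 6 L / 75% of flow,
    muscle 33 L / 18%, fat 14.5 L / 5%, vessel-poor 12 L / 2%, and a 5 L
    central blood pool.  Concentrations are stored as blood-equilibrium
    gas-equivalent fractions.
    """

    tissue_volumes: np.ndarray = field(
        default_factory=lambda: np.array([6.0, 33.0, 14.5, 12.0, 5.0])
    )
    flow_fractions: np.ndarray = field(
        default_factory=lambda: np.array([0.75, 0.18, 0.05, 0.02, 0.0])
    )
    tissue_blood_partition: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.0, 2.3, 1.0, 1.0])
    )
    blood_gas_partition: float = N2O_BLOOD_GAS_PARTITION
    tissue_concentrations: np.ndarray | None = None

    def __post_init__(self):
        self.tissue_volumes = np.asarray(self.tissue_volumes, dtype=float)
        self.flow_fractions = np.asarray(self.flow_fractions, dtype=float)
        self.tissue_blood_partition = np.asarray(
            self.tissue_blood_partition, dtype=float
        )
        if abs(self.flow_fractions.sum() - 1.0) > 1e-12:
            raise ConfigurationError("body flow fractions must sum to 1")
        if np.any(self.tissue_volumes <= 0):
            raise ConfigurationError("tissue volumes must be > 0")
        if not (self.blood_gas_partition > 0):
            raise ConfigurationError("blood_gas_partition must be > 0")
        if self.tissue_concentrations is None:
            self.tissue_concentrations = np.zeros_like(self.tissue_volumes)

    @property
    def n(self) -> int:
        return len(self.tissue_volumes)

    @property
    def gas_capacities(self) -> np.ndarray:
        """Gas-equivalent tracer capacity of each tissue (L of gas per unit fraction)."""
        return (
            self.blood_gas_partition
            * self.tissue_blood_partition
            * self.tissue_volumes
        )


def default_body() -> BodyCompartmentSet:
    """Fresh body compartment set with default tissue parameters."""
    return BodyCompartmentSet()


def build_lung(
    theta: ThetaParams,
    settings: VentilatorSettings,
    n_alv: int = 125,
    n_ds: int = 10,
) -> CompartmentalLung:
    """Construct the compartmental lung for parameters ``theta``.

    Equal alveolar compartment volumes ``V_A / n_alv``; ventilation and
    perfusion fractions from the lognormal quantile-midpoint discretisation;
    equal dead-space stage volumes; zero initial tracer.
    """
    if n_alv < 1 or n_ds < 1:
        raise ConfigurationError(
            f"need n_alv >= 1 and n_ds >= 1, got {n_alv}, {n_ds}"
        )
    lung = CompartmentalLung(
        alveolar_volumes=np.full(n_alv, theta.v_a / n_alv),
        vent_fractions=discretize_lognormal(theta.vent, n_alv),
        perf_fractions=discretize_lognormal(theta.perf, n_alv),
        deadspace_volumes=np.full(n_ds, settings.dead_space / n_ds),
        alveolar_concentrations=np.zeros(n_alv),
    )
    lung.validate()
    return lung


# --------------------------------------------------------------------------
# Dead-space chain transport
# --------------------------------------------------------------------------

class _DeadspaceChain:
    """Exact linear map for pushing a tidal volume through the serial stages.

    The push of volume ``Vx`` with constant inlet fraction ``u`` is resolved
    into ``m`` aliquots; each aliquot mixes into stage 1 and cascades through
    the chain (mix-then-overflow per stage).  Because each aliquot step is
    linear in (state, u), the whole push collapses to one precomputed affine
    map ``d' = P d + q u``; the tracer volume delivered downstream follows
    from exact conservation, ``out = Vx u - sum(v * (d' - d))``.
    """

    def __init__(self, stage_volumes: np.ndarray, push_volume: float):
        v = float(stage_volumes[0])
        if not np.allclose(stage_volumes, v):
            raise ConfigurationError("dead-space stages must have equal volumes")
        n = len(stage_volumes)
        self.stage_volume = v
        self.push_volume = push_volume
        # aliquot small vs stage volume => approach the plug-flow limit
        m = max(20, int(math.ceil(5.0 * push_volume / v)))
        delta = push_volume / m
        alpha = delta / (v + delta)
        beta = 1.0 - alpha
        # single-aliquot map M, r  (stage i gets beta*d_i + alpha*d'_{i-1})
        M = np.zeros((n, n))
        for i in range(n):
            for k in range(i + 1):
                M[i, k] = beta * alpha ** (i - k)
        r = alpha ** np.arange(1, n + 1)
        # compose m aliquots with constant inlet fraction
        P = np.linalg.matrix_power(M, m)
        S = np.eye(n)
        acc = np.eye(n)
        for _ in range(m - 1):
            acc = acc @ M
            S = S + acc
        self.P = P
        self.q = S @ r

    def push(self, d: np.ndarray, u: float) -> tuple[np.ndarray, float]:
        """Push ``push_volume`` of gas at inlet fraction ``u`` through stages.

        Returns the new stage fractions and the tracer volume (L) delivered
        at the outlet.
        """
        d_new = self.P @ d + self.q * u
        out = self.push_volume * u - self.stage_volume * (d_new.sum() - d.sum())
        return d_new, out


_CHAIN_CACHE: dict = {}


def _get_chain(stage_volumes: np.ndarray, push_volume: float) -> "_DeadspaceChain":
    """Memoised chain construction (depends only on ventilator settings)."""
    key = (len(stage_volumes), round(float(stage_volumes[0]), 12), round(push_volume, 12))
    chain = _CHAIN_CACHE.get(key)
    if chain is None:
        chain = _CHAIN_CACHE[key] = _DeadspaceChain(np.asarray(stage_volumes, float), push_volume)
    return chain


# --------------------------------------------------------------------------
# Breath engine
# --------------------------------------------------------------------------

class BreathEngine:
    """One-breath state-transition engine shared by all simulation paths.

    State vector layout: ``[deadspace fractions (mouth first), alveolar
    fractions, body tissue concentrations]``.  Every sub-step (chain push,
    tidal mixing, implicit exchange, venous update) is linear in the state and
    the inspired fraction, so the whole breath is an affine map; the
    single-compartment recovery exploits this via :meth:`linear_operator`.
    """

    def __init__(
        self,
        lung: CompartmentalLung,
        body: BodyCompartmentSet | None,
        settings: VentilatorSettings,
    ):
        self.settings = settings
        self.n_ds = lung.n_deadspace
        self.n_alv = lung.n_alveolar
        self.n_body = 0 if body is None else body.n
        self.vx = settings.alveolar_tidal_volume
        self.chain = _get_chain(lung.deadspace_volumes, self.vx)
        self.w = lung.vent_fractions.copy()
        self.pf = lung.perf_fractions.copy()
        self.v_alv = lung.alveolar_volumes.copy()
        self.v_infl = self.v_alv + self.w * self.vx
        if body is not None:
            lam = body.blood_gas_partition
            self.ff = body.flow_fractions.copy()
            self.cap = body.gas_capacities
        else:
            lam = N2O_BLOOD_GAS_PARTITION
            self.ff = np.zeros(0)
            self.cap = np.zeros(0)
        self.lam = lam
        self.has_body = body is not None
        self.k = np.zeros(self.n_alv)

    def configure_flow(self, q_p: float):
        """Set pulmonary blood flow (L/min); per-breath blood volume Q_P/RR."""
        q_b = q_p / self.settings.respiratory_rate
        self.k = self.lam * q_b * self.pf / self.v_infl

    def initial_state(self) -> np.ndarray:
        return np.zeros(self.n_ds + self.n_alv + self.n_body)

    def split(self, x: np.ndarray):
        nd, na = self.n_ds, self.n_alv
        return x[:nd], x[nd : nd + na], x[nd + na :]

    def step(self, x: np.ndarray, u: float):
        """Advance one breath.

        Returns ``(x_new, f_et, f_mixed_exp, uptake, f_venous)``.
        """
        d, f, c = self.split(x)
        f_ven = float(self.ff @ c) if self.has_body else 0.0

        # (1) inspiration: tidal gas transits the dead-space chain and is
        # shared among compartments in proportion to ventilation fractions
        d_new, delivered = self.chain.push(d, u)
        f_del = delivered / self.vx
        f = (self.v_alv * f + self.w * self.vx * f_del) / self.v_infl

        # (2) gas exchange, implicit in the end-of-step alveolar fraction:
        # flux_i = lam*(Q_P/RR)*pf_i*(F_i' - F_ven) with F_i' the post-exchange
        # fraction (unconditionally stable for any perfusion-to-volume ratio)
        f_post = (f + self.k * f_ven) / (1.0 + self.k)
        uptake_i = self.v_infl * (f - f_post)
        uptake = float(uptake_i.sum())
        f = f_post

        # (4) body compartments receive the uptake in proportion to flow
        if self.has_body:
            c = c.copy()
            nz = self.ff > 0
            c[nz] = c[nz] + self.ff[nz] * uptake / self.cap[nz]
            f_ven = float(self.ff @ c)

        # (3) expiration: compartments empty back through the chain; end-tidal
        # is the ventilation-weighted alveolar fraction, mixed-expired the
        # volume-weighted mouth output including dead-space washout
        f_et = float(self.w @ f)
        d_rev, expired = self.chain.push(d_new[::-1], f_et)
        d_new = d_rev[::-1]
        f_me = expired / self.vx

        x_new = np.concatenate([d_new, f, c])
        return x_new, f_et, f_me, uptake, f_ven

    def linear_operator(self):
        """Probe the breath map for its exact affine form ``x' = T x + g u``.

        Built by evaluating :meth:`step` on unit vectors, so any fast path
        using it is algebraically identical to the direct loop.  Also returns
        the output rows for end-tidal fraction (``f_et = c_et @ x_new``) and
        per-breath uptake (``U = a_upt @ x + b_upt * u``).
        """
        n = self.n_ds + self.n_alv + self.n_body
        g, _, _, b_upt, _ = self.step(np.zeros(n), 1.0)
        T = np.empty((n, n))
        a_upt = np.empty(n)
        e = np.zeros(n)
        for i in range(n):
            e[i] = 1.0
            T[:, i], _, _, a_upt[i], _ = self.step(e, 0.0)
            e[i] = 0.0
        # end-tidal output row: f_et = w @ F_new = c_et @ x_new
        c_et = np.zeros(n)
        c_et[self.n_ds : self.n_ds + self.n_alv] = self.w
        return T, g, c_et, a_upt, b_upt


# --------------------------------------------------------------------------
# Breath series record
# --------------------------------------------------------------------------

_SERIES_COLUMNS = [
    "breath_index",
    "t_start_s",
    "f_insp",
    "f_et",
    "f_mixed_exp",
    "uptake",
    "f_venous",
]


@dataclass
class BreathSeries:
    """Breath-by-breath tracer record produced by :func:`simulate`."""

    t_start: np.ndarray
    f_insp: np.ndarray
    f_et: np.ndarray
    f_mixed_exp: np.ndarray
    uptake: np.ndarray
    f_venous: np.ndarray
    mass_residual: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.t_start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "breath_index": np.arange(len(self)),
                "t_start_s": self.t_start,
                "f_insp": self.f_insp,
                "f_et": self.f_et,
                "f_mixed_exp": self.f_mixed_exp,
                "uptake": self.uptake,
                "f_venous": self.f_venous,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "BreathSeries":
        df = pd.read_csv(path_or_buf)
        missing = set(_SERIES_COLUMNS) - set(df.columns)
        if missing:
            raise ConfigurationError(f"breath series CSV missing columns {missing}")
        return cls(
            t_start=df["t_start_s"].to_numpy(float),
            f_insp=df["f_insp"].to_numpy(float),
            f_et=df["f_et"].to_numpy(float),
            f_mixed_exp=df["f_mixed_exp"].to_numpy(float),
            uptake=df["uptake"].to_numpy(float),
            f_venous=df["f_venous"].to_numpy(float),
        )


# --------------------------------------------------------------------------
# Simulation driver
# --------------------------------------------------------------------------

def simulate(
    lung: CompartmentalLung,
    body: BodyCompartmentSet | None,
    settings: VentilatorSettings,
    forcing: SinewaveForcing,
    n_breaths: int,
    seed: int | None = None,
    q_p: float | None = None,
    initial_state: np.ndarray | None = None,
    t0: float = 0.0,
    engine: BreathEngine | None = None,
    return_state: bool = False,
):
    """Simulate ``n_breaths`` breaths and return the :class:`BreathSeries`.

    ``q_p`` is the pulmonary blood flow in L/min (0 disables uptake); the
    simulator itself is deterministic — ``seed`` is accepted for interface
    symmetry with noisy measurement generation and is unused here.  Pass
    ``initial_state``/``t0`` (from a previous call with ``return_state=True``)
    to continue a run.
    """
    if n_breaths < 1:
        raise ConfigurationError(f"n_breaths must be >= 1, got {n_breaths}")
    if engine is None:
        engine = BreathEngine(lung, body, settings)
        engine.configure_flow(0.0 if q_p is None else q_p)
    tb = settings.breath_duration
    t_insp_mid = 0.5 * tb * settings.ie_ratio / (1.0 + settings.ie_ratio)

    x = engine.initial_state() if initial_state is None else initial_state.copy()
    t_start = t0 + tb * np.arange(n_breaths)
    u = forcing.fraction_at(t_start + t_insp_mid)
    if np.any(u < 0) or np.any(u >= 1):
        raise UnphysicalForcingError("inspired fraction outside [0, 1)")

    f_et = np.empty(n_breaths)
    f_me = np.empty(n_breaths)
    upt = np.empty(n_breaths)
    f_ven = np.empty(n_breaths)
    resid = np.empty(n_breaths)
    vx = engine.vx
    v_alv = engine.v_alv
    v_ds = lung.deadspace_volumes
    for kb in range(n_breaths):
        d0, f0, _ = engine.split(x)
        stored0 = float(v_ds @ d0 + v_alv @ f0)
        x, f_et[kb], f_me[kb], upt[kb], f_ven[kb] = engine.step(x, u[kb])
        d1, f1, _ = engine.split(x)
        stored1 = float(v_ds @ d1 + v_alv @ f1)
        resid[kb] = vx * u[kb] - vx * f_me[kb] - upt[kb] - (stored1 - stored0)
        if f1.min() < -1e-9 or f1.max() > 1 + 1e-9:
            raise UnphysicalForcingError(
                f"alveolar fraction left [0, 1] at breath {kb}"
            )
    series = BreathSeries(
        t_start=t_start,
        f_insp=u,
        f_et=f_et,
        f_mixed_exp=f_me,
        uptake=upt,
        f_venous=f_ven,
        mass_residual=resid,
    )
    if return_state:
        return series, x
    return series
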