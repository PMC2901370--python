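"""Physical model of microarray hybridization and post-hybridization washing.

The measured (net, background-subtracted) intensity of a 25-mer probe is
modelled as a two-species Langmuir adsorption isotherm whose specific (S) and
non-specific (N) contributions are attenuated by mode-specific washing
survival fractions ``w``::

    I(t) = M * b(t) * (X_S * w_S(t) + X_N * w_N(t)) / (1 + X_S + X_N)

``X = K * [h]`` is the dimensionless binding strength (binding constant times
transcript concentration), ``M`` the saturation intensity and ``b(t)`` an
optional bleaching factor (fixed to 1 by default -- repeated scanning was
found to bleach negligibly).

Washing after ``t`` stringent cycles follows first-order desorption with a
rate tied to the binding constant through a power law, ``k = (K0/K)**gamma``:
weakly bound targets wash off fast, strongly bound ones survive.  Expressed
against the initial intensity this yields a sigmoidal survival function with
limiting levels ``w_min``/``w_max`` and a critical intensity
``I_crit = a'*M/(1+a')`` at which the normalized kernel equals 1/e.

Ensemble-averaged quantities instead decay as a power law of the cycle
number, ``log10 w(t) = -eta*log10 t``, equivalent to a hyperbolically
decaying effective rate -- the signature of heterogeneous desorption.

All hook-facing logarithms are decadic; kernel exponentials are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "HybridizationParams",
    "WashingParams",
    "occupancy_after_wash",
    "intensity",
    "dissociation_rate",
    "washing_kernel",
    "survival_vs_intensity",
    "critical_intensity",
    "sigmoid_washing_parameters",
    "powerlaw_survival",
    "effective_rate",
    "extrapolate_tstar",
    "enrichment_two_rounds",
    "two_component_decay",
]

TAU_INF = math.inf  # sentinel for "no measurable decay"


@dataclass
class HybridizationParams:
    """Planted or estimated physical constants of one hybridization.

    ``M`` is the saturation intensity (linear units), ``O`` the optical
    background, ``b`` the bleaching factor (1.0 = no bleaching), ``K_*`` the
    binding constants (1/pM), ``conc_*`` transcript concentrations (pM) and
    ``X_*`` the resulting dimensionless binding strengths ``K * conc``.
    """

    M: float
    O: float = 0.0
    b: float = 1.0
    K_S_PM: float = 0.0
    K_S_MM: float = 0.0
    K_N: float = 0.0
    conc_S: float = 0.0
    conc_N: float = 0.0

    def __post_init__(self) -> None:
        if not self.M > self.O >= 0:
            raise ValueError(f"require M > O >= 0, got M={self.M}, O={self.O}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"bleaching factor b must lie in [0,1], got {self.b}")
        for name in ("K_S_PM", "K_S_MM", "K_N", "conc_S", "conc_N"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def X_S_PM(self) -> float:
        return self.K_S_PM * self.conc_S

    @property
    def X_S_MM(self) -> float:
        return self.K_S_MM * self.conc_S

    @property
    def X_N(self) -> float:
        return self.K_N * self.conc_N


@dataclass
class WashingParams:
    """Parameters of the washing kinetics.

    ``w_min``/``w_max`` are the limiting survival fractions actually observed
    (complete wash-off and perfectly unwashed probes do not occur), ``gamma``
    the critical exponent of the rate/constant power law, ``a`` the scale
    parameter whose cycle-dependent form is ``a' = a * t**(1/gamma)``, and
    ``eta`` an optional ensemble power-law exponent.
    """

    w_min: float = 0.06
    w_max: float = 0.9
    gamma: float = 1.6
    a: float = 0.1
    K0: float = 1.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_min < self.w_max <= 1.0:
            raise ValueError(
                f"require 0 <= w_min < w_max <= 1, got ({self.w_min}, {self.w_max})"
            )
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.a <= 0:
            raise ValueError("scale parameter a must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")

    def a_prime(self, t: float) -> float:
        """Cycle-rescaled scale parameter ``a' = a * t**(1/gamma)``."""
        if t < 0:
            raise ValueError("washing cycles t must be non-negative")
        return self.a * t ** (1.0 / self.gamma)

    @classmethod
    def from_a_prime(cls, a_prime: float, t_ref: float, **kwargs) -> "WashingParams":
        """Build from the rescaled scale ``a'`` quoted at reference cycle ``t_ref``."""
        gamma = kwargs.get("gamma", 1.6)
        return cls(a=a_prime / t_ref ** (1.0 / gamma), **kwargs)


def occupancy_after_wash(
    X_S: ArrayLike, X_N: ArrayLike, w_S: ArrayLike, w_N: ArrayLike
) -> ArrayLike:
    """Total probe occupancy surviving washing.

    ``(X_N*w_N + X_S*w_S) / (1 + X_N + X_S)`` -- the equilibrium two-species
    isotherm with the bound fractions weighted by their survival.  With
    ``w_S = w_N = 1`` this is the plain equilibrium occupancy.
    """
    X_S, X_N, w_S, w_N = map(np.asarray, (X_S, X_N, w_S, w_N))
    if np.any(X_S < 0) or np.any(X_N < 0) or np.any(w_S < 0) or np.any(w_N < 0):
        raise ValueError("binding strengths and survival fractions must be >= 0")
    if np.any(w_S > 1) or np.any(w_N > 1):
        raise ValueError("survival fractions must be <= 1")
    theta = (X_N * w_N + X_S * w_S) / (1.0 + X_N + X_S)
    return theta if theta.ndim else float(theta)


def intensity(params: HybridizationParams, occupancy: ArrayLike) -> ArrayLike:
    """Net (background-subtracted) intensity ``I = M * b * Theta``."""
    occ = np.asarray(occupancy)
    if np.any(occ < 0) or np.any(occ > 1):
        raise ValueError("occupancy must lie in [0, 1]")
    out = params.M * params.b * occ
    return out if out.ndim else float(out)


def dissociation_rate(K: ArrayLike, K0: float, gamma: float) -> ArrayLike:
    """Per-cycle desorption rate ``k = (K0/K)**gamma``.

    The rate decreases with the binding constant: stable duplexes resist
    washing.  ``K0`` and ``gamma`` are sequence-independent scaling constants.
    """
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("binding constant K must be positive")
    if K0 <= 0:
        raise ValueError("reference constant K0 must be positive")
    out = (K0 / K) ** gamma
    return out if out.ndim else float(out)


def washing_kernel(
    k: ArrayLike, t: ArrayLike, w_min: float = 0.0, w_max: float = 1.0
) -> ArrayLike:
    """Survival after ``t`` cycles at rate ``k``.

    Bounded exponential decay ``w = w_min + (w_max - w_min) * exp(-k*t)``;
    with the default bounds this is the bare first-order washing function.
    """
    k, t = np.asarray(k, dtype=float), np.asarray(t, dtype=float)
    if np.any(k < 0) or np.any(t < 0):
        raise ValueError("rate and cycle count must be non-negative")
    if not 0.0 <= w_min < w_max <= 1.0:
        raise ValueError("require 0 <= w_min < w_max <= 1")
    out = w_min + (w_max - w_min) * np.exp(-k * t)
    return out if out.ndim else float(out)


def critical_intensity(wp: WashingParams, t: float, M: float) -> float:
    """Intensity at which the normalized kernel equals 1/e: ``a'M/(1+a')``."""
    ap = wp.a_prime(t)
    return ap * M / (1.0 + ap)


def survival_vs_intensity(
    I0: ArrayLike, M: float, wp: WashingParams, t: float
) -> ArrayLike:
    """Sigmoidal survival fraction as a function of the initial intensity.

    Inverts the single-mode isotherm ``I0 = M*X/(1+X)`` for the binding
    strength and feeds the resulting rate into the bounded kernel::

        w(I0) = w_min + (w_max - w_min) * exp(-[a' * (M - I0)/I0]**gamma)

    with ``a' = a * t**(1/gamma)``.  Monotone increasing in ``I0`` with a
    step centered at the critical intensity ``a'M/(1+a')``.
    """
    I0 = np.asarray(I0, dtype=float)
    if np.any(I0 <= 0) or np.any(I0 > M):
        raise ValueError("initial intensity must satisfy 0 < I0 <= M")
    ap = wp.a_prime(t)
    kernel = np.exp(-((ap * (M - I0) / I0) ** wp.gamma))
    out = wp.w_min + (wp.w_max - wp.w_min) * kernel
    return out if out.ndim else float(out)


def sigmoid_washing_parameters(
    I0: ArrayLike,
    M: float,
    wp: WashingParams,
    t_long: float = 17.0,
    t_short: float = 2.0,
) -> tuple[ArrayLike, ArrayLike]:
    """Predicted decay-curve summary parameters for a probe of intensity I0.

    Returns ``(w_inf, tau)``: the asymptotic survival evaluated at the long
    timepoint (default 17 cycles) and the short-time decay constant
    ``tau = -t_short / ln w(t_short)``.  Both step sigmoidally from
    ``(w_min, tau_min)`` up to ``(w_max, tau_max)`` with increasing ``I0``;
    ``tau`` is ``+inf`` where the short-time survival is 1.
    """
    w_inf = survival_vs_intensity(I0, M, wp, t_long)
    w_short = np.asarray(survival_vs_intensity(I0, M, wp, t_short), dtype=float)
    with np.errstate(divide="ignore"):
        log_w = np.log(w_short)
    tau = np.where(log_w < 0, -t_short / np.where(log_w < 0, log_w, -1.0), TAU_INF)
    if np.ndim(w_inf) == 0:
        return float(w_inf), float(tau)
    return w_inf, tau


def powerlaw_survival(eta: float, t: ArrayLike) -> ArrayLike:
    """Ensemble survival ``w(t) = t**(-eta)`` (``log10 w = -eta*log10 t``)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("power-law survival is defined for t >= 1")
    if eta < 0:
        raise ValueError("eta must be non-negative")
    out = t ** (-eta)
    return out if out.ndim else float(out)


def effective_rate(eta: float, t: ArrayLike) -> ArrayLike:
    """Slowly varying rate ``k(t) = eta * ln(t)/t`` implied by the power law.

    ``w(t) = exp(-k(t)*t)`` with this hyperbolically decaying rate equals
    ``t**(-eta)``: washing slows down as weakly bound duplexes deplete.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError("effective rate is defined for t >= 1")
    out = eta * np.log(t) / t
    return out if out.ndim else float(out)


def extrapolate_tstar(eta: float) -> float:
    """Cycles needed for a tenfold signal reduction, ``t* = 0.1**(-1/eta)``."""
    if eta <= 0:
        return math.inf
    return 0.1 ** (-1.0 / eta)


def enrichment_two_rounds(
    w: float, label_increment: float = 1.0
) -> tuple[float, float]:
    """Bright-duplex bookkeeping for two staining/washing rounds.

    Only labelled (bright) duplexes wash off; dark ones persist and a second
    staining relabels a fresh ``label_increment`` of the initial bright level.
    Starting from bright level 1, round one leaves ``w``; restaining raises
    the bright level to ``label_increment + w`` and the second wash leaves
    ``(label_increment + w) * w``.  Returns that final bright level and the
    round-2/round-1 enrichment factor ``label_increment + w`` (per unit
    survivor) -- e.g. ``w = 0.9`` gives 171% of the initial level and a
    factor 1.9.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("survival fraction w must lie in [0, 1]")
    if label_increment < 0:
        raise ValueError("label increment must be non-negative")
    bright_round1 = w
    bright_round2 = (label_increment + w) * w
    if bright_round1 == 0.0:
        return 0.0, label_increment
    return bright_round2, bright_round2 / bright_round1


def two_component_decay(t: ArrayLike, w_inf: float, tau: float) -> ArrayLike:
    """Empirical fast + asymptotic decay ``w(t) = (1-w_inf)*exp(-t/tau) + w_inf``.

    Proxy for the multiphase decay of heterogeneously bound targets: a fast
    short-time component with decay constant ``tau`` cycles and a long-time
    plateau ``w_inf`` subsuming the slow component.
    """
    t = np.asarray(t, dtype=float)
    if math.isinf(tau):  # exp(-t/inf) = 1: no decay at all
        out = np.ones_like(t)
        return out if out.ndim else float(out)
    out = (1.0 - w_inf) * np.exp(-t / tau) + w_inf
    return out if out.ndim else float(out)
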