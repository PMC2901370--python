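"""Estimation of washing kinetics from multi-timepoint probe intensities.

Two complementary descriptions are extracted:

* **per-probe decay summaries** -- for each probe the asymptotic survival
  ``w_inf = I(17)/I(0)`` and the short-time decay constant
  ``tau = -2/ln(I(2)/I(0))`` (cycles), whose sigmoidal dependence on the
  initial intensity is fitted with the bounded survival kernel to recover
  ``(w_min, w_max, gamma, a')``;

* **ensemble power laws** -- each hook summary parameter is a log-scale
  quantity whose washing kinetics follow ``Psi(t) - Psi(1) = eta * log10 t``
  for ``t > 1``; the slopes are linear combinations of the per-mode washing
  exponents ``eta^{P,h}`` of ``log10 w(t) = -eta * log10 t`` and can be
  inverted for them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .hook_analysis import HookParameters
from .synthetic_chip import ChipSeries, ProbeRecord
from .wash_model import TAU_INF, WashingParams

__all__ = [
    "ProbeDecayFit",
    "KineticSlopes",
    "WashingExponents",
    "SigmoidFitError",
    "probe_decay_fit",
    "probe_decay_fits",
    "moving_average_vs_logI0",
    "fit_sigmoid",
    "hook_param_kinetics",
    "invert_washing_exponents",
    "slopes_from_exponents",
]


class SigmoidFitError(RuntimeError):
    """Sigmoid survival fit failed (non-convergence or one-sided data)."""


@dataclass
class ProbeDecayFit:
    """Decay summary of one probe: survival plateau and short-time constant."""

    probe_id: str
    w_inf: float
    tau: float
    logI0: float


@dataclass
class KineticSlopes:
    """Power-law slopes ``eta`` of the hook parameters versus log10 cycles."""

    eta_sigma_start: float
    eta_sigma_end: float
    eta_alpha: float
    eta_beta: float
    eta_R: float
    eta_phi: float = math.nan
    eta_O: float = math.nan
    se: dict = field(default_factory=dict)


@dataclass
class WashingExponents:
    """Per-mode washing exponents of ``log10 w(t) = -eta * log10 t``."""

    eta_N: float
    eta_PM_S: float
    eta_MM_S: float
    consistency_residual: float = math.nan
    alternative: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (self.eta_N >= self.eta_MM_S >= self.eta_PM_S >= -1e-9):
            warnings.warn(
                "washing exponents violate the expected ordering "
                f"eta_N >= eta_MM_S >= eta_PM_S >= 0: "
                f"({self.eta_N:.3f}, {self.eta_MM_S:.3f}, {self.eta_PM_S:.3f})")


def _ratio_summaries(I0, I_short, I_long, t_short=2.0):
    """Vectorized w_inf / tau estimators with (0, 1] ratio clipping."""
    with np.errstate(divide="ignore", invalid="ignore"):
        w_inf = np.clip(I_long / I0, 1e-12, 1.0)
        r_short = np.clip(I_short / I0, 1e-12, 1.0)
        log_r = np.log(r_short)
        tau = np.where(log_r < 0, -t_short / np.where(log_r < 0, log_r, -1.0),
                       TAU_INF)
    return w_inf, tau


def probe_decay_fit(
    record: ProbeRecord,
    timepoints: Sequence[int] = (0, 2, 17),
    method: str = "ratio",
) -> ProbeDecayFit:
    """Decay summary of a single probe.

    The default ``ratio`` method uses the 0/2/17-cycle intensities directly:
    ``w_inf = I(17)/I(0)`` and ``tau = -2/ln(I(2)/I(0))``, with intensity
    ratios clipped to (0, 1] before the logarithm (noise can push a ratio
    above 1, in which case ``tau`` is the +inf sentinel).  ``method='fit'``
    instead least-squares fits the two-component decay
    ``w(t) = (1 - w_inf)*exp(-t/tau) + w_inf`` across all available
    timepoints of the record.
    """
    t0, t_short, t_long = timepoints
    missing = [t for t in timepoints if t not in record.intensities]
    if missing:
        raise ValueError(f"probe {record.set_id}/{record.pair_index} misses "
                         f"timepoints {missing}")
    I0 = record.intensities[t0]
    if I0 <= 0:
        raise ValueError("initial intensity must be positive")
    probe_id = f"{record.set_id}:{record.pair_index}:{record.probe_type}"
    if method == "ratio":
        w_inf, tau = _ratio_summaries(
            np.float64(I0), np.float64(record.intensities[t_short]),
            np.float64(record.intensities[t_long]), t_short=float(t_short))
        return ProbeDecayFit(probe_id=probe_id, w_inf=float(w_inf),
                             tau=float(tau), logI0=math.log10(I0))
    if method != "fit":
        raise ValueError("method must be 'ratio' or 'fit'")
    ts = np.array(sorted(record.intensities), dtype=float)
    ws = np.clip(np.array([record.intensities[t] for t in sorted(
        record.intensities)]) / I0, 1e-12, 1.0)
    if np.ptp(ws) < 1e-12:  # constant series: no decay
        return ProbeDecayFit(probe_id=probe_id, w_inf=1.0, tau=TAU_INF,
                             logI0=math.log10(I0))
    from .wash_model import two_component_decay

    popt, _ = curve_fit(
        lambda t, w_inf, tau: two_component_decay(t, w_inf, tau),
        ts, ws, p0=[max(float(ws[-1]), 1e-3), 2.0],
        bounds=([1e-6, 1e-3], [1.0, 1e3]), maxfev=10000)
    return ProbeDecayFit(probe_id=probe_id, w_inf=float(popt[0]),
                         tau=float(popt[1]), logI0=math.log10(I0))


def probe_decay_fits(
    series: ChipSeries,
    t_short: int = 2,
    t_long: int = 17,
) -> pd.DataFrame:
    """Decay summaries for every probe of a series (vectorized).

    Returns a frame aligned with ``series.probes`` carrying ``set_id``,
    ``probe_type``, ``logI0``, ``w_inf``, ``tau`` and the count of ratios
    clipped at 1.  Probes with non-positive initial intensity are dropped.
    """
    for t in (0, t_short, t_long):
        if t not in series.timepoints:
            raise ValueError(f"series misses required timepoint t={t}")
    I0 = series.intensities(0)
    Is = series.intensities(t_short)
    Il = series.intensities(t_long)
    ok = I0 > 0
    w_inf, tau = _ratio_summaries(I0[ok], Is[ok], Il[ok], t_short=float(t_short))
    out = series.probes.loc[ok, ["set_id", "pair_index", "probe_type"]].copy()
    out["logI0"] = np.log10(I0[ok])
    out["w_inf"] = w_inf
    out["tau"] = tau
    out.attrs["n_clipped"] = int((Il[ok] > I0[ok]).sum() + (Is[ok] > I0[ok]).sum())
    return out


def moving_average_vs_logI0(
    fits: pd.DataFrame,
    window: int = 1000,
) -> pd.DataFrame:
    """Moving average of the probe decay summaries along log10 I(0).

    Probes are sorted by initial intensity and each output point averages
    exactly ``window`` consecutive probes (the window is shrunk with a
    warning when fewer probes are available).  Infinite ``tau`` values are
    excluded from the tau average.
    """
    df = fits.sort_values("logI0", ignore_index=True)
    n = len(df)
    if n < window:
        warnings.warn(f"only {n} probes available; shrinking window from "
                      f"{window} to {n}")
        window = n
    kernel = np.ones(window) / window
    logI0 = np.convolve(df["logI0"].to_numpy(), kernel, mode="valid")
    w_inf = np.convolve(df["w_inf"].to_numpy(), kernel, mode="valid")
    tau = df["tau"].to_numpy()
    finite = np.isfinite(tau)
    tau_sum = np.convolve(np.where(finite, tau, 0.0), np.ones(window), "valid")
    tau_cnt = np.convolve(finite.astype(float), np.ones(window), "valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        tau_mean = np.where(tau_cnt > 0, tau_sum / tau_cnt, np.nan)
    return pd.DataFrame({"logI0": logI0, "w_inf": w_inf, "tau": tau_mean})


def fit_sigmoid(
    curve: pd.DataFrame,
    M: float,
    value: str = "w_inf",
) -> dict:
    """Fit the bounded sigmoid survival kernel to a smoothed w_inf curve.

    Least squares on the log10 survival scale of
    ``w(I0) = w_min + (w_max - w_min) * exp(-(a'(M - I0)/I0)**gamma)``.
    Returns the fitted ``(w_min, w_max, gamma, a_prime)`` with standard
    errors, the implied critical intensity ``I_crit = a'M/(1+a')`` and the
    fit RMS.  Raises :class:`SigmoidFitError` when the curve does not span
    both plateaus or the optimizer fails.
    """
    logI0 = curve["logI0"].to_numpy(dtype=float)
    w = curve[value].to_numpy(dtype=float)
    ok = np.isfinite(w) & (w > 0)
    logI0, w = logI0[ok], w[ok]
    if len(w) < 8:
        raise SigmoidFitError("too few points for a sigmoid fit")
    span = np.max(w) / np.min(w)
    if span < 1.5:
        raise SigmoidFitError(
            f"curve spans only a {span:.2f}-fold survival range; both "
            "plateaus are required for a sigmoid fit")
    I0 = 10.0 ** logI0

    def model_log(I, w_min, w_max, gamma, a_prime):
        arg = np.clip(a_prime * (M - I) / np.clip(I, 1e-12, None), 0.0, None)
        return np.log10(w_min + (w_max - w_min) * np.exp(-(arg ** gamma)))

    w_min0 = max(float(np.min(w)) * 0.95, 1e-3)
    w_max0 = min(float(np.max(w)) * 1.05, 1.0)
    mid = math.sqrt(w_min0 * w_max0)
    i_mid = I0[int(np.argmin(np.abs(w - mid)))]
    a0 = min(max(i_mid / max(M - i_mid, 1e-9), 1e-4), 10.0)
    try:
        popt, pcov = curve_fit(
            model_log, I0, np.log10(w),
            p0=[w_min0, w_max0, 1.5, a0],
            bounds=([1e-6, 1e-3, 0.05, 1e-6], [1.0, 1.0, 20.0, 100.0]),
            maxfev=20000)
    except RuntimeError as exc:
        raise SigmoidFitError(f"sigmoid fit did not converge: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    w_min, w_max, gamma, a_prime = (float(v) for v in popt)
    resid = model_log(I0, *popt) - np.log10(w)
    return {
        "w_min": w_min, "w_max": w_max, "gamma": gamma, "a_prime": a_prime,
        "se": {"w_min": se[0], "w_max": se[1], "gamma": se[2], "a_prime": se[3]},
        "I_crit": a_prime * M / (1.0 + a_prime),
        "logI_crit": math.log10(a_prime * M / (1.0 + a_prime)),
        "rms": float(np.sqrt(np.mean(resid**2))),
    }


_PSI_FIELDS = ("sigma_start", "sigma_end", "alpha", "beta")


def _slope(logt: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and standard error of y against log10 t."""
    A = np.column_stack([logt, np.ones_like(logt)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    n = len(y)
    if n > 2 and res.size:
        s2 = float(res[0]) / (n - 2)
        cov = s2 * np.linalg.inv(A.T @ A)
        return float(coef[0]), float(np.sqrt(cov[0, 0]))
    return float(coef[0]), math.nan


def hook_param_kinetics(
    params: Sequence[HookParameters],
    timepoints: Sequence[int],
    O: Optional[dict] = None,
) -> KineticSlopes:
    """Power-law slopes of the hook parameters over the washing series.

    Ordinary least squares of each log-scale summary against ``log10 t``
    using the timepoints with ``t > 1`` (the t = 0 and t = 1 scans anchor the
    power law but cannot enter a log fit).  Requires at least three such
    timepoints.
    """
    tps = np.asarray(timepoints, dtype=float)
    if len(tps) != len(params):
        raise ValueError("one HookParameters per timepoint required")
    use = tps > 1.0
    if use.sum() < 3:
        raise ValueError(
            f"need >= 3 timepoints with t > 1 for slope fits, got {int(use.sum())}")
    logt = np.log10(tps[use])
    values = {f: np.array([getattr(p, f) for p in params])[use] for f in _PSI_FIELDS}
    values["R"] = np.log10(np.array([p.mean_R for p in params])[use])
    values["phi"] = np.array([p.phi for p in params])[use]
    if O is not None:
        values["O"] = np.log10(np.array([O[int(t)] for t in tps], dtype=float)[use])
    slopes, ses = {}, {}
    for name, y in values.items():
        if not np.all(np.isfinite(y)):
            slopes[name], ses[name] = math.nan, math.nan
            continue
        slopes[name], ses[name] = _slope(logt, y)
    return KineticSlopes(
        eta_sigma_start=slopes["sigma_start"], eta_sigma_end=slopes["sigma_end"],
        eta_alpha=slopes["alpha"], eta_beta=slopes["beta"], eta_R=slopes["R"],
        eta_phi=slopes.get("phi", math.nan), eta_O=slopes.get("O", math.nan),
        se=ses)


def invert_washing_exponents(
    slopes: KineticSlopes,
    residual_threshold: float = 0.1,
) -> WashingExponents:
    """Per-mode washing exponents from the hook-parameter slopes.

    The start coordinate tracks the non-specific survival
    (``eta_N = -eta_sigma_start``), the S/N ratio adds the PM-specific one
    (``eta_PM_S = eta_N - eta_R``) and the hook height the MM/PM contrast
    (``eta_MM_S = eta_PM_S + eta_alpha``).  The endpoint provides the
    overdetermined check ``-2*eta_sigma_end = eta_PM_S + eta_MM_S``; when its
    residual exceeds the threshold a warning is emitted and the alternative
    endpoint-based solution is reported alongside.
    """
    for name in ("eta_sigma_start", "eta_R", "eta_alpha"):
        if not math.isfinite(getattr(slopes, name)):
            raise ValueError(f"required slope {name} is not finite")
    eta_N = -slopes.eta_sigma_start
    eta_PM_S = eta_N - slopes.eta_R
    eta_MM_S = eta_PM_S + slopes.eta_alpha
    residual = math.nan
    alternative = None
    if math.isfinite(slopes.eta_sigma_end):
        residual = (-2.0 * slopes.eta_sigma_end) - (eta_PM_S + eta_MM_S)
        if abs(residual) > residual_threshold:
            # endpoint-based solution keeps the alpha contrast, rescales the mean
            mean_end = -slopes.eta_sigma_end
            alternative = {
                "eta_PM_S": mean_end - slopes.eta_alpha / 2.0,
                "eta_MM_S": mean_end + slopes.eta_alpha / 2.0,
            }
            warnings.warn(
                f"exponent consistency residual {residual:.3f} exceeds "
                f"{residual_threshold}; reporting endpoint-based alternative")
    return WashingExponents(eta_N=eta_N, eta_PM_S=eta_PM_S, eta_MM_S=eta_MM_S,
                            consistency_residual=residual, alternative=alternative)


def slopes_from_exponents(
    eta_N: float, eta_PM_S: float, eta_MM_S: float
) -> KineticSlopes:
    """Hook-parameter slopes implied by per-mode washing exponents.

    The forward map of :func:`invert_washing_exponents`; used as the
    algebraic roundtrip oracle.
    """
    return KineticSlopes(
        eta_sigma_start=-eta_N,
        eta_sigma_end=-(eta_PM_S + eta_MM_S) / 2.0,
        eta_alpha=eta_MM_S - eta_PM_S,
        eta_beta=eta_N,  # beta = logM - sigma_start with logM time-invariant
        eta_R=eta_N - eta_PM_S)
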