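"""Washing-corrected calibration of probe intensities into binding strengths.

Inverting the washed two-species isotherm

    I = M * (X_S * w_S + X_N * w_N) / (1 + X_S + X_N)

for the specific binding strength gives the basic calibration equation

    X_S = [I * (1 + X_N) - M * X_N * w_N] / (M * w_S - I),

which corrects the measured net intensity for non-specific hybridization,
saturation and post-hybridization washing at once.  Setting the survivals to
one recovers the plain Langmuir estimate used by wash-unaware calibration.
Because washing attenuates the apparent saturation and background, the
Langmuir estimate is biased low -- mildly at intermediate expression, sharply
at both ends of the range.

The survival fractions may be fixed per mode or driven by the probe
occupancy itself through the sigmoidal survival kernel, whose argument must
then be shifted from the unwashed to the measured (washed) intensity --
a fixed-point problem solved here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .hook_analysis import HookParameters
from .sensitivity import SensitivityProfile, predict_delta_logI
from .synthetic_chip import ChipSeries
from .wash_model import WashingParams, survival_vs_intensity

__all__ = [
    "SaturationError",
    "CalibrationInputs",
    "CalibrationResult",
    "calibrate_probe",
    "calibrate_probes",
    "occupancy_washing_function",
    "estimate_logM",
    "probe_background",
]


class SaturationError(ValueError):
    """Measured intensity at or above the (washed) saturation ceiling."""


@dataclass
class CalibrationInputs:
    """Inputs of a single-probe calibration.

    ``logX_N`` is the probe's *washed* non-specific binding strength
    ``log10(X_N * w_N)`` as estimated by the hook analysis.  The washing
    model is either the fixed pair ``(w_S, w_N)`` or, when
    ``washing_params``/``t`` are set, the occupancy-driven survival
    ``w(Theta)`` applied to both modes.
    """

    I: float
    logM: float
    logX_N: float
    w_S: float = 1.0
    w_N: float = 1.0
    washing_params: Optional[WashingParams] = None
    t: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.w_S <= 1.0 and 0.0 < self.w_N <= 1.0):
            raise ValueError("survival fractions must lie in (0, 1]")
        if not math.isfinite(self.logX_N):
            raise ValueError("logX_N must be finite")


@dataclass
class CalibrationResult:
    logX_S_washed: float
    logX_S_langmuir: float
    bias: float  # logX_S_langmuir - logX_S_washed, <= 0
    flags: list = field(default_factory=list)


def _invert_isotherm(I, M, Y_N, w_S, w_N):
    """Vectorized inversion of the washed isotherm; returns (X_S, clipped)."""
    X_N = Y_N / w_N
    numer = I * (1.0 + X_N) - M * Y_N
    denom = M * w_S - I
    X_S = numer / denom
    clipped = X_S < 0
    return np.where(clipped, 0.0, X_S), clipped


def calibrate_probes(
    I: np.ndarray,
    logM: float,
    logX_N: np.ndarray,
    w_S: float = 1.0,
    w_N: float = 1.0,
    washing_params: Optional[WashingParams] = None,
    t: Optional[float] = None,
) -> dict:
    """Vectorized washed + Langmuir calibration of many probes.

    Returns arrays ``logX_S_washed``, ``logX_S_langmuir`` and ``bias`` plus a
    boolean ``clipped`` mask for intensities below the background-implied
    floor (specific strength clipped to 0, log reported as -inf).
    """
    I = np.asarray(I, dtype=float)
    logX_N = np.broadcast_to(np.asarray(logX_N, dtype=float), I.shape)
    M = 10.0 ** logM
    if washing_params is not None:
        if t is None:
            raise ValueError("occupancy-driven washing requires the cycle count t")
        theta = np.clip(I / M, 1e-12, 1.0 - 1e-12)
        w = np.array([occupancy_washing_function(th, washing_params, t)
                      for th in np.atleast_1d(theta)])
        w = w.reshape(I.shape)
        w_S_eff, w_N_eff = w, w
    else:
        w_S_eff, w_N_eff = w_S, w_N
    if np.any(I >= M):
        raise SaturationError("intensity at or above the saturation intensity M")
    if np.any(I >= M * np.asarray(w_S_eff)):
        raise SaturationError(
            "intensity at or above the washed saturation ceiling M*w_S")
    Y_N = 10.0 ** logX_N
    X_washed, clip_w = _invert_isotherm(I, M, Y_N, w_S_eff, w_N_eff)
    X_langmuir, clip_l = _invert_isotherm(I, M, Y_N, 1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lw = np.log10(X_washed)
        ll = np.log10(X_langmuir)
        bias = ll - lw  # nan when both estimates clip to zero
    return {
        "logX_S_washed": lw,
        "logX_S_langmuir": ll,
        "bias": bias,
        "clipped": clip_w | clip_l,
    }


def calibrate_probe(inputs: CalibrationInputs) -> CalibrationResult:
    """Washed and Langmuir specific binding strengths of one probe.

    With ``w_S = w_N = 1`` both estimates coincide and the bias vanishes;
    otherwise the Langmuir estimate underestimates the true strength
    (negative bias), increasingly so toward the background floor and the
    saturation ceiling.
    """
    res = calibrate_probes(
        np.asarray([inputs.I]), inputs.logM, np.asarray([inputs.logX_N]),
        w_S=inputs.w_S, w_N=inputs.w_N,
        washing_params=inputs.washing_params, t=inputs.t)
    flags = ["clipped to zero"] if bool(res["clipped"][0]) else []
    return CalibrationResult(
        logX_S_washed=float(res["logX_S_washed"][0]),
        logX_S_langmuir=float(res["logX_S_langmuir"][0]),
        bias=float(res["bias"][0]),
        flags=flags,
    )


def occupancy_washing_function(
    theta: float,
    wp: WashingParams,
    t: float,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Survival fraction as a function of the *washed* probe occupancy.

    The sigmoid kernel takes the unwashed intensity, but a routine experiment
    measures only the washed one: ``I(t) = I(0) * w``.  Substituting gives
    the fixed-point problem ``w = f(I(t)/w)`` with ``f`` the survival versus
    initial intensity (evaluated on the occupancy scale, ``I0/M = theta/w``).
    Solved by damped fixed-point iteration with a bracketing (Brent) fallback;
    monotone increasing in ``theta``.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("occupancy must lie in (0, 1)")
    if theta >= wp.w_max:  # occupancy after washing cannot exceed w_max
        return wp.w_max

    def f(w):
        return float(survival_vs_intensity(min(theta / w, 1.0), 1.0, wp, t))

    w = max(theta, wp.w_min)
    for _ in range(max_iter):
        w_new = f(w)
        w_new = max(w_new, theta)  # I(0) = I(t)/w may not exceed M
        if abs(w_new - w) < tol:
            return w_new
        w = 0.5 * (w + w_new)
    lo, hi = max(theta, 1e-12), 1.0
    try:
        return float(brentq(lambda x: x - f(x), lo, hi, xtol=tol))
    except ValueError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            f"occupancy washing fixed point did not converge at theta={theta}"
        ) from exc


def estimate_logM(
    series: ChipSeries,
    n_top: int = 50,
    timepoint: Optional[int] = None,
    hook_logM: Optional[float] = None,
) -> float:
    """Saturation intensity from the brightest PM probes.

    The most intense PM probes of a chip are taken as saturated, so their
    mean log10 intensity estimates ``log M_max``; 20-100 probes suffice.
    Typically ``M_max >= M`` from the hook fit -- when the estimate instead
    falls well below a supplied hook value, no saturated probes are present
    and a warning is emitted.
    """
    if not 1 <= n_top:
        raise ValueError("n_top must be >= 1")
    t = series.timepoints[0] if timepoint is None else timepoint
    pm = series.probes.loc[series.probes["probe_type"] == "PM",
                           ChipSeries.intensity_column(t)].to_numpy()
    pm = pm[pm > 0]
    if len(pm) < n_top:
        raise ValueError(f"need at least n_top={n_top} PM probes")
    top = np.sort(np.log10(pm))[-n_top:]
    est = float(np.mean(top))
    if hook_logM is not None and est < hook_logM - 0.3:
        import warnings

        warnings.warn(
            f"top-probe estimate logM={est:.2f} falls below the hook value "
            f"{hook_logM:.2f}; the chip may carry no saturated probes")
    return est


def probe_background(
    hook: HookParameters,
    profile: SensitivityProfile,
    sequences,
    center_sequences=None,
) -> np.ndarray:
    """Probe-specific washed non-specific strength ``log10(X_N * w_N)``.

    Combines the chip-level mean from the hook geometry,
    ``<log10 X_N*w_N> = sigma_start - logM = -beta``, with the sequence
    increment from the non-specific sensitivity profile.  Increments are
    centered over ``center_sequences`` (default: the query sequences), so the
    ensemble mean reproduces the hook-level value exactly.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    mean_level = hook.sigma_start - hook.logM
    inc = np.atleast_1d(predict_delta_logI(sequences, profile))
    if center_sequences is None:
        offset = float(np.mean(inc))
    else:
        offset = float(np.mean(
            np.atleast_1d(predict_delta_logI(center_sequences, profile))))
    return mean_level + inc - offset
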