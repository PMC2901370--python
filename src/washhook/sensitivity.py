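"""Positional nucleotide sensitivity profiles of probe intensities.

Within a probe set all probes see the same transcript concentration, so the
residual ``delta log I = log10 I - <log10 I>_set`` is driven by the sequence
dependence of the binding constant (and, after washing, of the survival
fraction).  The single-base model approximates the residual as a sum of
position- and letter-specific terms,

    delta log I_p ~ sum_k sigma_k(B_pk),

under the constraint that at every position the four letter terms sum to
zero.  The nearest-neighbour variant uses the 16 dinucleotides at the 24
adjacent position pairs instead.  Washing amplifies the profiles: survival
is itself an increasing function of the binding constant, so the sequence
contrast grows and the difference profile "washed - unwashed" is
proportional to the underlying positional affinity terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic_chip import ChipSeries, SEQ_LEN, sequence_codes

__all__ = [
    "SensitivityProfile",
    "DifferenceProfile",
    "SINGLE_LETTERS",
    "NN_LETTERS",
    "fit_profile",
    "difference_profile",
    "predict_delta_logI",
    "write_profile",
]

SINGLE_LETTERS = tuple("ACGT")
NN_LETTERS = tuple(a + b for a in "ACGT" for b in "ACGT")


@dataclass
class SensitivityProfile:
    """Fitted position x letter sensitivity matrix (log10-intensity units)."""

    model: str  # "single" or "nn"
    values: np.ndarray  # (25, 4) or (24, 16)
    ensemble: str = ""
    timepoint: int = 0
    r2: float = math.nan
    n_probes: int = 0

    def __post_init__(self) -> None:
        expected = (SEQ_LEN, 4) if self.model == "single" else (SEQ_LEN - 1, 16)
        if self.values.shape != expected:
            raise ValueError(f"{self.model} profile must have shape {expected}")

    @property
    def letters(self) -> tuple:
        return SINGLE_LETTERS if self.model == "single" else NN_LETTERS

    def check_constraints(self, tol: float = 1e-8) -> None:
        worst = float(np.max(np.abs(self.values.sum(axis=1))))
        if worst > tol:
            raise AssertionError(f"letter sums deviate from zero by {worst}")


@dataclass
class DifferenceProfile:
    """Washing increment of a sensitivity profile (after minus before)."""

    model: str
    values: np.ndarray
    ensemble: str = ""


def _nn_codes(codes: np.ndarray) -> np.ndarray:
    return 4 * codes[:, :-1] + codes[:, 1:]


def _design(codes: np.ndarray, model: str) -> np.ndarray:
    """Centered one-hot design (sum-to-zero contrasts per position)."""
    if model == "single":
        pos_codes, n_letters = codes, 4
    elif model == "nn":
        pos_codes, n_letters = _nn_codes(codes), 16
    else:
        raise ValueError("model must be 'single' or 'nn'")
    n, npos = pos_codes.shape
    X = np.zeros((n, npos * n_letters))
    cols = pos_codes + np.arange(npos)[None, :] * n_letters
    X[np.arange(n)[:, None], cols] = 1.0
    X -= 1.0 / n_letters
    return X


def fit_profile(
    series: ChipSeries,
    ensemble_sets: Sequence[str],
    timepoint: int,
    model: str = "single",
    ensemble_label: str = "",
    probe_type: Optional[str] = None,
) -> SensitivityProfile:
    """Least-squares sensitivity profile of one probe ensemble.

    The response is the set-centered log10 intensity; the design uses
    centered (sum-to-zero) letter contrasts per position and the minimum-norm
    least-squares solution, which lands exactly on the zero-letter-sum
    constraint manifold.  Probes with non-positive intensity are dropped;
    positions where the ensemble carries fewer than two distinct letters are
    reported as degenerate.
    """
    col = ChipSeries.intensity_column(timepoint)
    df = series.probes
    mask = df["set_id"].isin(set(ensemble_sets))
    if probe_type is not None:
        mask &= df["probe_type"] == probe_type
    sub = df.loc[mask, ["set_id", "sequence", col]]
    sub = sub[sub[col] > 0]
    n_params = SEQ_LEN * 4 if model == "single" else (SEQ_LEN - 1) * 16
    if len(sub) < 10 * (n_params - (SEQ_LEN if model == "single" else SEQ_LEN - 1)):
        raise ValueError(
            f"ensemble of {len(sub)} probes is too small for {n_params} parameters")
    logI = np.log10(sub[col].to_numpy())
    y = logI - sub.groupby("set_id")[col].transform(
        lambda v: np.mean(np.log10(v))).to_numpy()

    codes = sequence_codes(sub["sequence"].to_numpy())
    pos_codes = codes if model == "single" else _nn_codes(codes)
    n_letters = 4 if model == "single" else 16
    degenerate = [int(k) for k in range(pos_codes.shape[1])
                  if len(np.unique(pos_codes[:, k])) < 2]
    if degenerate:
        raise ValueError(f"degenerate sequence positions (single letter): "
                         f"{degenerate}")
    X = _design(codes, model)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    values = coef.reshape(-1, n_letters)
    fitted = X @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    prof = SensitivityProfile(model=model, values=values,
                              ensemble=ensemble_label, timepoint=timepoint,
                              r2=r2, n_probes=len(sub))
    # the minimum-norm solution satisfies the letter-sum constraint; enforce
    # exactly against numerical drift
    prof.values -= prof.values.mean(axis=1, keepdims=True)
    return prof


def difference_profile(
    after: SensitivityProfile, before: SensitivityProfile
) -> DifferenceProfile:
    """Washing difference profile ``sigma(after) - sigma(before)``."""
    if after.model != before.model or after.values.shape != before.values.shape:
        raise ValueError("profiles must share model and shape")
    if after.ensemble != before.ensemble:
        raise ValueError("profiles must refer to the same probe ensemble")
    return DifferenceProfile(model=after.model,
                             values=after.values - before.values,
                             ensemble=after.ensemble)


def predict_delta_logI(sequences, profile: SensitivityProfile) -> np.ndarray:
    """Predicted log10 intensity increments for 25-mer sequences."""
    if isinstance(sequences, str):
        sequences = [sequences]
    codes = sequence_codes(np.asarray(sequences))
    pos_codes = codes if profile.model == "single" else _nn_codes(codes)
    npos = pos_codes.shape[1]
    out = profile.values[np.arange(npos)[None, :], pos_codes].sum(axis=1)
    return out if len(out) > 1 else float(out[0])


def write_profile(profile: SensitivityProfile, path) -> None:
    """Tab-delimited profile matrix with metadata header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#model\t{profile.model}\n")
        fh.write(f"#ensemble\t{profile.ensemble}\n")
        fh.write(f"#timepoint\t{profile.timepoint}\n")
        fh.write(f"#r2\t{profile.r2!r}\n")
        fh.write(f"#n_probes\t{profile.n_probes}\n")
        frame = pd.DataFrame(profile.values, columns=list(profile.letters))
        frame.insert(0, "position", np.arange(1, len(frame) + 1))
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")
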