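"""Synthetic GeneChip-style probe-level data with planted ground truth.

Emulates the structure of a PM/MM expression array washing experiment: probe
sets of (by default) 11 perfect-match/mismatch pairs of 25-mers, a specific
transcript concentration drawn per set (zero for non-expressed sets), a pooled
non-specific background strength per probe, and net intensities at a series of
stringent-wash timepoints.  Every probe carries its planted binding strengths
and survival fractions so that downstream estimators can be validated against
the truth.

Two washing drivers are available, mirroring the two analysis routes:

``sigmoid``
    one survival kernel for all probes, a sigmoidal function of the probe's
    unwashed intensity (strongly bound = bright = unwashable);
``powerlaw``
    per-mode ensemble power laws ``w(t) = t**-eta`` with separate exponents
    for non-specific, PM-specific and MM-specific duplexes.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .wash_model import WashingParams, powerlaw_survival, survival_vs_intensity

__all__ = [
    "LETTERS",
    "ProbeRecord",
    "ChipConfig",
    "ChipSeries",
    "TableFormatError",
    "generate_sequences",
    "default_epsilon_profile",
    "planted_affinities",
    "generate_chip_series",
    "apply_relabeling",
    "write_table",
    "read_table",
]

LETTERS = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
MIDDLE = 12  # 0-based index of the 13th base, the GeneChip mismatch position
SEQ_LEN = 25

REQUIRED_COLUMNS = ("set_id", "pair_index", "probe_type", "sequence")


class TableFormatError(ValueError):
    """Raised when a probe table file does not match the expected layout."""


@dataclass
class ProbeRecord:
    """One physical probe with its intensity trace and optional truth."""

    set_id: str
    pair_index: int
    probe_type: str  # "PM" or "MM"
    sequence: str
    intensities: dict[int, float] = field(default_factory=dict)
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != SEQ_LEN:
            raise ValueError(f"sequence must have length {SEQ_LEN}")
        if self.probe_type not in ("PM", "MM"):
            raise ValueError("probe_type must be 'PM' or 'MM'")


@dataclass
class ChipConfig:
    """Study conditions of a simulated washing series.

    Defaults reproduce a desk-scale chip: 5000 probe sets of 11 PM/MM pairs
    (vs. ~6e5 probes on a real array), 35% of sets expressed with specific
    concentrations log-normal over roughly 1e-2..1e3 pM, saturation intensity
    ``M = 10**4.5``, wash timepoints 0/2/3/7/17 cycles and a multiplicative
    log-normal intensity noise of 15% per scan.
    """

    n_sets: int = 5000
    n_pairs: int = 11
    expressed_fraction: float = 0.35
    logS_mean: float = 1.0
    logS_sd: float = 1.2
    conc_N: float = 300.0
    logK_S_mean: float = -2.0
    logK_N_mean: float = -5.0
    sigma_set: float = 0.3
    alpha0: float = 1.0  # PM-MM decrement of the specific log10 binding constant
    epsilon_scale: float = 0.05
    M: float = 10**4.5
    O0: float = 50.0
    eta_O: float = 0.1
    noise_cv: float = 0.15
    timepoints: tuple[int, ...] = (0, 2, 3, 7, 17)
    washing: str = "sigmoid"  # or "powerlaw"
    # sigmoid survival quoted at 17 cycles: w_min=0.06, w_max=0.9, gamma=1.6, a'=0.1
    washing_params: WashingParams = field(
        default_factory=lambda: WashingParams.from_a_prime(0.1, 17.0))
    eta_N: float = 0.5
    eta_PM_S: float = 0.03
    eta_MM_S: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 1 or self.n_pairs < 1:
            raise ValueError("n_sets and n_pairs must be >= 1")
        if not 0.0 <= self.expressed_fraction <= 1.0:
            raise ValueError("expressed_fraction must lie in [0, 1]")
        if self.washing not in ("sigmoid", "powerlaw"):
            raise ValueError("washing driver must be 'sigmoid' or 'powerlaw'")
        if 0 not in self.timepoints:
            raise ValueError("timepoints must include the unwashed scan t = 0")
        if tuple(sorted(self.timepoints)) != tuple(self.timepoints):
            raise ValueError("timepoints must be sorted ascending")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if isinstance(self.washing_params, dict):
            self.washing_params = WashingParams(**self.washing_params)

    @classmethod
    def from_dict(cls, d: dict) -> "ChipConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "timepoints" in d:
            d["timepoints"] = tuple(int(t) for t in d["timepoints"])
        return cls(**d)


@dataclass
class ChipSeries:
    """Probe table plus chip-level metadata for one washing series.

    ``probes`` holds one row per physical probe with columns ``set_id``,
    ``pair_index``, ``probe_type``, ``sequence`` and one net-intensity column
    ``I_{t}`` per wash timepoint.  ``truth`` (same row order) carries the
    planted binding strengths and survival fractions when simulated.
    """

    probes: pd.DataFrame
    timepoints: tuple[int, ...]
    O: dict[int, float]
    M: float
    seed: int = 0
    clip_at: Optional[float] = None
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.probes.columns]
        if missing:
            raise TableFormatError(f"probe table misses columns {missing}")
        for t in self.timepoints:
            if self.intensity_column(t) not in self.probes.columns:
                raise TableFormatError(f"missing intensity column I_{t}")
        o_vals = [self.O[t] for t in self.timepoints]
        if any(b > a + 1e-9 for a, b in zip(o_vals, o_vals[1:])):
            raise ValueError("optical background O(t) must be non-increasing")

    @staticmethod
    def intensity_column(t: int) -> str:
        return f"I_{int(t)}"

    def intensities(self, t: int) -> np.ndarray:
        return self.probes[self.intensity_column(t)].to_numpy(dtype=float)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def iter_records(self):
        """Yield :class:`ProbeRecord` views (convenience, not the fast path)."""
        cols = [self.intensity_column(t) for t in self.timepoints]
        for i, row in enumerate(self.probes.itertuples(index=False)):
            intens = {t: getattr(row, c) for t, c in zip(self.timepoints, cols)}
            truth = None if self.truth is None else self.truth.iloc[i].to_dict()
            yield ProbeRecord(row.set_id, int(row.pair_index), row.probe_type,
                              row.sequence, intens, truth)


def generate_sequences(n_sets: int, n_pairs: int = 11, seed: int = 0) -> pd.DataFrame:
    """Random 25-mer PM probes with their middle-base-complement MM partners.

    Returns a frame of ``2 * n_sets * n_pairs`` rows ordered PM/MM within each
    pair; reproducible for a given seed.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    n_probes = n_sets * n_pairs
    codes = rng.integers(0, 4, size=(n_probes, SEQ_LEN))
    pm_seqs = ["".join(s) for s in LETTERS[codes]]
    mm_seqs = [s[:MIDDLE] + _COMPLEMENT[s[MIDDLE]] + s[MIDDLE + 1:] for s in pm_seqs]
    set_ids = np.repeat([f"set{(i + 1):05d}" for i in range(n_sets)], n_pairs)
    pair_idx = np.tile(np.arange(1, n_pairs + 1), n_sets)
    frame = pd.DataFrame({
        "set_id": np.repeat(set_ids, 2),
        "pair_index": np.repeat(pair_idx, 2),
        "probe_type": np.tile(["PM", "MM"], n_probes),
        "sequence": np.column_stack([pm_seqs, mm_seqs]).ravel(),
    })
    return frame


def default_epsilon_profile(scale: float = 0.05) -> np.ndarray:
    """Smooth planted position x letter affinity profile (25 x 4, rows sum 0).

    Parabola-shaped positional weight peaking mid-sequence; cytosine
    stabilizes, adenine destabilizes (the qualitative single-base pattern of
    hybridization affinity), G/T carry smaller opposite terms.
    """
    k = np.arange(SEQ_LEN)
    shape = 1.0 - ((k - (SEQ_LEN - 1) / 2) / ((SEQ_LEN - 1) / 2)) ** 2  # 0..1..0
    prof = np.zeros((SEQ_LEN, 4))
    prof[:, 0] = -scale * shape          # A
    prof[:, 1] = scale * shape           # C
    prof[:, 2] = 0.4 * scale * shape     # G
    prof[:, 3] = -0.4 * scale * shape    # T
    return prof


def sequence_codes(sequences) -> np.ndarray:
    """Integer-encode sequences (A,C,G,T -> 0..3) into an (n, 25) array."""
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(-1, SEQ_LEN)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for i, ch in enumerate(b"ACGT"):
        codes[arr == ch] = i
    if (codes < 0).any():
        raise ValueError("sequences contain letters outside {A,C,G,T}")
    return codes


def _profile_sums(codes: np.ndarray, profile: np.ndarray) -> np.ndarray:
    return profile[np.arange(SEQ_LEN)[None, :], codes].sum(axis=1)


def planted_affinities(
    records: pd.DataFrame,
    epsilon_profile: np.ndarray,
    k0_mean: float = -2.0,
    sigma_set: float = 0.3,
    seed: int = 0,
    kN_mean: float = -5.0,
    alpha0: float = 1.0,
) -> pd.DataFrame:
    """Per-probe planted log10 binding constants.

    ``log10 K_S = k0_mean + set offset + sum_k eps_k(B_pk)`` for PM probes,
    reduced by the fixed decrement ``alpha0`` for their MM partner (the
    middle mismatch).  The non-specific constant ``log10 K_N`` uses the same
    positional profile on the PM sequence and is shared by both probes of a
    pair (PM and MM hybridize identically with non-specific targets).
    """
    epsilon_profile = np.asarray(epsilon_profile, dtype=float)
    if epsilon_profile.shape != (SEQ_LEN, 4):
        raise ValueError(f"epsilon profile must be {SEQ_LEN} x 4")
    if np.max(np.abs(epsilon_profile.sum(axis=1))) > 1e-8:
        raise ValueError("epsilon profile rows must sum to zero at each position")
    rng = np.random.default_rng(seed)
    set_ids, set_pos = np.unique(records["set_id"], return_inverse=True)
    set_offset = rng.normal(0.0, sigma_set, size=len(set_ids))[set_pos]

    codes = sequence_codes(records["sequence"].to_numpy())
    eps_sum = _profile_sums(codes, epsilon_profile)
    is_mm = (records["probe_type"] == "MM").to_numpy()

    logK_S = k0_mean + set_offset + eps_sum - alpha0 * is_mm
    # non-specific affinity: keyed to the PM sequence, shared within the pair
    pm_eps = eps_sum.copy()
    pm_eps[is_mm] = eps_sum[~is_mm]  # rows ordered PM, MM within each pair
    logK_N = kN_mean + pm_eps
    return pd.DataFrame({"logK_S": logK_S, "logK_N": logK_N}, index=records.index)


def generate_chip_series(config: ChipConfig) -> ChipSeries:
    """Simulate a full multi-timepoint washing series with planted truth."""
    rng = np.random.default_rng(config.seed)
    probes = generate_sequences(config.n_sets, config.n_pairs, seed=config.seed)
    profile = default_epsilon_profile(config.epsilon_scale)
    aff = planted_affinities(
        probes, profile, k0_mean=config.logK_S_mean, sigma_set=config.sigma_set,
        seed=config.seed + 1, kN_mean=config.logK_N_mean, alpha0=config.alpha0,
    )

    n_expressed = int(round(config.expressed_fraction * config.n_sets))
    expressed = np.zeros(config.n_sets, dtype=bool)
    expressed[rng.choice(config.n_sets, size=n_expressed, replace=False)] = True
    logS = rng.normal(config.logS_mean, config.logS_sd, size=config.n_sets)
    conc_S_set = np.where(expressed, 10.0 ** logS, 0.0)
    conc_S = np.repeat(conc_S_set, config.n_pairs * 2)

    X_S = 10.0 ** aff["logK_S"].to_numpy() * conc_S
    X_N = 10.0 ** aff["logK_N"].to_numpy() * config.conc_N
    is_mm = (probes["probe_type"] == "MM").to_numpy()

    denom = 1.0 + X_S + X_N
    I0_clean = config.M * (X_S + X_N) / denom

    truth = {"logK_S": aff["logK_S"].to_numpy(), "logK_N": aff["logK_N"].to_numpy(),
             "conc_S": conc_S, "X_S": X_S, "X_N": X_N}
    sigma_ln = np.sqrt(np.log1p(config.noise_cv**2))
    O = {}
    for t in config.timepoints:
        if config.washing == "sigmoid":
            if t == 0:
                w = np.ones_like(I0_clean)
            else:
                w = survival_vs_intensity(
                    np.clip(I0_clean, 1e-12, config.M), config.M,
                    config.washing_params, t)
            w_S, w_N = w, w
            I_clean = I0_clean * w
        else:
            if t == 0:
                w_N = np.ones_like(X_N)
                w_S = np.ones_like(X_S)
            else:
                w_N = np.full_like(X_N, powerlaw_survival(config.eta_N, t))
                w_S = np.where(is_mm, powerlaw_survival(config.eta_MM_S, t),
                               powerlaw_survival(config.eta_PM_S, t))
            I_clean = config.M * (X_S * w_S + X_N * w_N) / denom
        if config.noise_cv > 0:
            noise = np.exp(rng.normal(0.0, sigma_ln, size=I_clean.shape))
            I_obs = I_clean * noise
        else:
            I_obs = I_clean
        probes[ChipSeries.intensity_column(t)] = I_obs
        truth[f"w_S_{t}"] = w_S
        truth[f"w_N_{t}"] = w_N
        truth[f"I_clean_{t}"] = I_clean
        O[t] = config.O0 * (1.0 if t < 1 else float(powerlaw_survival(config.eta_O, t)))

    return ChipSeries(
        probes=probes, timepoints=tuple(config.timepoints), O=O, M=config.M,
        seed=config.seed, truth=pd.DataFrame(truth, index=probes.index),
    )


def apply_relabeling(
    series: ChipSeries,
    clip_at: Optional[float] = None,
    label_increment: float = 1.0,
) -> ChipSeries:
    """Second staining/washing series derived from a simulated first one.

    Only labelled duplexes are washable; restaining converts the same amount
    of dark duplexes to bright as the first round did, so each hybridization
    mode is enriched by ``label_increment + w_mode`` where ``w_mode`` is its
    survival over the full first series.  Optionally clips at the scanner
    ceiling ``clip_at``, producing a point mass of saturated readings.
    """
    if series.truth is None:
        raise ValueError("relabeling requires a series with planted truth")
    if clip_at is not None and clip_at <= 0:
        raise ValueError("clip_at must be positive")
    t_last = series.timepoints[-1]
    tr = series.truth
    X_S, X_N = tr["X_S"].to_numpy(), tr["X_N"].to_numpy()
    denom = 1.0 + X_S + X_N
    enrich_S = label_increment + tr[f"w_S_{t_last}"].to_numpy()
    enrich_N = label_increment + tr[f"w_N_{t_last}"].to_numpy()

    probes = series.probes.copy()
    truth = series.truth.copy()
    for t in series.timepoints:
        c_S = series.M * X_S * tr[f"w_S_{t}"].to_numpy() / denom
        c_N = series.M * X_N * tr[f"w_N_{t}"].to_numpy() / denom
        total = c_S + c_N
        factor = np.where(total > 0, (c_S * enrich_S + c_N * enrich_N)
                          / np.where(total > 0, total, 1.0), label_increment + 1.0)
        col = ChipSeries.intensity_column(t)
        new = probes[col].to_numpy() * factor
        if clip_at is not None and np.isfinite(clip_at):
            new = np.minimum(new, clip_at)
        probes[col] = new
        truth[f"I_clean_{t}"] = np.minimum(total * factor, clip_at) \
            if clip_at is not None and np.isfinite(clip_at) else total * factor
    return ChipSeries(probes=probes, timepoints=series.timepoints, O=dict(series.O),
                      M=series.M, seed=series.seed, clip_at=clip_at, truth=truth)


def write_table(series: ChipSeries, path) -> None:
    """Write a chip series as a tab-delimited probe table.

    Chip-level metadata travels in ``#key\\tvalue`` comment lines before the
    header row; the planted truth (if any) goes to a ``<path>.truth.tsv``
    sidecar so that the main table mirrors what a real experiment provides.
    """
    path = Path(path)
    meta = {
        "timepoints": ",".join(str(t) for t in series.timepoints),
        "M": repr(series.M),
        "O": ",".join(f"{t}:{series.O[t]!r}" for t in series.timepoints),
        "seed": str(series.seed),
    }
    if series.clip_at is not None:
        meta["clip_at"] = repr(series.clip_at)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}\t{v}\n")
        series.probes.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    if series.truth is not None:
        series.truth.to_csv(path.with_suffix(path.suffix + ".truth.tsv"),
                            sep="\t", index=False)


def read_table(path) -> ChipSeries:
    """Read a probe table written by :func:`write_table` (truth if present)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    n_meta = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_meta += 1
        try:
            key, value = line[1:].rstrip("\n").split("\t", 1)
        except ValueError:
            raise TableFormatError(f"{path}, line {n_meta}: malformed metadata line")
        meta[key] = value
    if "timepoints" not in meta:
        raise TableFormatError(f"{path}: missing '#timepoints' metadata line")
    try:
        probes = pd.read_csv(io.StringIO("".join(lines[n_meta:])), sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableFormatError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in probes.columns]
    if missing:
        raise TableFormatError(
            f"{path}, line {n_meta + 1}: header misses columns {missing}")
    timepoints = tuple(int(t) for t in meta["timepoints"].split(","))
    O = {}
    for item in meta.get("O", "").split(","):
        if item:
            t, v = item.split(":")
            O[int(t)] = float(v)
    truth_path = path.with_suffix(path.suffix + ".truth.tsv")
    truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else None
    clip = float(meta["clip_at"]) if "clip_at" in meta else None
    return ChipSeries(probes=probes, timepoints=timepoints, O=O,
                      M=float(meta.get("M", "nan")), seed=int(meta.get("seed", 0)),
                      clip_at=clip, truth=truth)
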