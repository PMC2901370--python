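# washhook

Probe-level calibration of PM/MM expression microarrays (Affymetrix
GeneChip-style) with explicit modelling of **post-hybridization washing**.

Stringent washing removes weakly bound targets from the array before
scanning.  It is essential for the signal-to-noise ratio, but it also deforms
the adsorption isotherm that calibration methods invert: calibration that
ignores washing systematically underestimates expression, most severely for
weakly and very highly expressed transcripts.  `washhook` is aimed at people
who work with probe-level intensity data — it models the physics, estimates
the washing kinetics from multi-timepoint wash/scan series, and corrects
expression estimates for the washing bias on single chips.

## Model

The net intensity of a 25-mer probe `P` (PM or MM) after `t` stringent wash
cycles is a washed two-species Langmuir isotherm

```
I^P(t) = M · (X_S^P · w^{P,S}(t) + X_N · w^{P,N}(t)) / (1 + X_S^P + X_N)
```

with binding strengths `X = K·[transcript]` for specific (S) and non-specific
(N) hybridization, saturation intensity `M`, and survival fractions `w`.
Desorption is first order with a rate tied to the binding constant by a power
law, `k = (K0/K)^γ`, which makes survival a sigmoidal function of the
unwashed intensity,

```
w(I0) = w_min + (w_max − w_min) · exp(−[a′·(M − I0)/I0]^γ),   a′ = a·t^{1/γ},
```

stepping from `w_min` to `w_max` at the critical intensity
`I_crit = a′M/(1 + a′)` (where the kernel equals `1/e`).  Ensemble averages
instead follow power laws of the cycle number, `log10 w(t) = −η·log10 t` —
the signature of heterogeneous binding — with separate exponents per
hybridization mode (`η_N`, `η_PM,S`, `η_MM,S`).

Chip-wide, everything is read off the **hook curve**: probe sets plotted as
`Δ = ⟨log10 I_PM − log10 I_MM⟩` versus `Σ = ½⟨log10 I_PM + log10 I_MM⟩` and
smoothed.  Its start gives the washed background `log10(M·X_N·w_N)`, its
height `α` the PM/MM gain, its width `β` the inverse background strength and
its endpoint the saturation level.  Washing slopes of these parameters are
linear combinations of the mode exponents and can be inverted for them.
Inverting the isotherm per probe yields the washing-corrected specific
binding strength (the expression measure) and quantifies the bias of the
plain Langmuir estimate.

## Modules

| module | contents |
|---|---|
| `washhook.wash_model` | isotherm, washing kernels, power laws, two-round staining/washing enrichment |
| `washhook.synthetic_chip` | chip simulator with planted truth; TSV probe-table I/O |
| `washhook.hook_analysis` | Δ/Σ transform, hook fits (exact & standard), S/N ratios, regime classification, washing-level hook |
| `washhook.wash_kinetics` | per-probe decay summaries, sigmoid kernel fits, hook-parameter slopes, exponent inversion |
| `washhook.sensitivity` | positional single-base / nearest-neighbour sensitivity profiles and washing difference profiles |
| `washhook.calibration` | washing-corrected binding strengths, Langmuir bias, occupancy-driven washing function |
| `washhook.cli` | `washhook simulate / hook / kinetics / sensitivity / calibrate` |

## Worked example

Simulate a 5000-set washing series (wash/scan at 0, 2, 3, 7, 17 cycles,
per-mode power-law washing, 15% intensity noise), fit the hook at every
timepoint and invert the kinetic slopes for the washing exponents:

```python
from washhook.synthetic_chip import ChipConfig, generate_chip_series
from washhook.hook_analysis import analyze_series
from washhook.wash_kinetics import hook_param_kinetics, invert_washing_exponents
from washhook.wash_model import extrapolate_tstar

config = ChipConfig(n_sets=5000, washing="powerlaw", noise_cv=0.15, seed=42)
series = generate_chip_series(config)

params = analyze_series(series)
for t, p in zip(series.timepoints, params):
    print(f"t={t:2d}  Sigma_start={p.sigma_start:6.3f}  alpha={p.alpha:5.3f}  "
          f"beta={p.beta:5.3f}  logM={p.logM:5.3f}")

slopes = hook_param_kinetics(params, series.timepoints, O=series.O)
expo = invert_washing_exponents(slopes)
print(f"eta_N    = {expo.eta_N:.3f}   t* = {extrapolate_tstar(expo.eta_N):.0f} cycles")
print(f"eta_PM_S = {expo.eta_PM_S:.3f}   t* = {extrapolate_tstar(expo.eta_PM_S):.2g} cycles")
print(f"eta_MM_S = {expo.eta_MM_S:.3f}   t* = {extrapolate_tstar(expo.eta_MM_S):.2g} cycles")
```

prints

```
t= 0  Sigma_start= 1.969  alpha=1.011  beta=2.544  logM=4.513
t= 2  Sigma_start= 1.819  alpha=1.061  beta=2.694  logM=4.513
t= 3  Sigma_start= 1.731  alpha=1.088  beta=2.782  logM=4.513
t= 7  Sigma_start= 1.547  alpha=1.143  beta=2.966  logM=4.513
t=17  Sigma_start= 1.355  alpha=1.208  beta=3.158  logM=4.513
eta_N    = 0.499   t* = 101 cycles
eta_PM_S = 0.030   t* = 4.1e+33 cycles
eta_MM_S = 0.187   t* = 2.2e+05 cycles
```

Reading this: washing drags the hook start down (the non-specific background
falls as `t^-0.5`, so ~100 further cycles would cut it tenfold) while the
hook grows wider and taller — MM-bound specific targets wash off with
exponent ≈ 0.19, whereas PM-bound specific targets (η ≈ 0.03) are for
practical purposes unwashable.  The simulator planted
`η_N = 0.5, η_PM,S = 0.03, η_MM,S = 0.18`, all recovered within ±0.01 here.

The same run from a shell:

```sh
washhook simulate --seed 42 --out chip.tsv
washhook kinetics chip.tsv --out kinetics/
washhook calibrate chip.tsv --timepoint 17 --out calibrated.tsv
```

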