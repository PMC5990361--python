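# fretquant

Calibration and quantification pipeline for semisynthetic ratiometric FRET
biosensors of free NAD⁺ and free NADPH/NADP⁺ (SNAP/Halo-tag "Snifit"-type
sensors built on human sepiapterin reductase, labeled with a TMR donor and a
SiR acceptor). It is written for people who run these sensors — on a plate
reader, a widefield microscope, a TCSPC-FLIM confocal, or a flow cytometer —
and need to turn raw readouts into free cofactor concentrations and redox
ratios with honest error handling, plus fully synthetic test data for every
acquisition mode.

## The model

The sensor is a two-state switch (open/low-FRET ↔ closed/high-FRET) whose
equilibrium is set by the analyte. On the **emission-ratio scale**
(R = donor/acceptor intensity) the response is a single binding isotherm:

    R(c) = R_max + (R_min − R_max) / (1 + c50/c)          (analyte axis)
    R(q) = R_min + (R_max − R_min) / (1 + r50/q)          (q = NADPH/NADP⁺)

inverted for quantification as

    NADPH/NADP⁺ = r50 · (R − R_min)/(R_max − R)
    [NAD⁺]      = c50 · (R_max − R)/(R − R_min)

On the **FRET-efficiency scale** (E, from fluorescence lifetimes,
E = 1 − ⟨τ_DA⟩/⟨τ_D⟩ with amplitude-weighted mean lifetimes
⟨τ⟩ = Σαᵢτᵢ/Σαᵢ) the readout is affine in occupancy and uses the
occupancy-scale half-saturation constants:

    NADPH/NADP⁺ = K₅₀ · (E_max − E)/(E − E_min)
    [NAD⁺]      = K_D′ · (E − E_min)/(E_max − E)

Around this core the package implements: isotherm and isosbestic-normalized
occupancy fits of titration data; first/second-order switching and labeling
kinetics; widefield ratio imaging (flat-field/background correction,
bleed-through correction FRET_c = FRET_raw − α·TMR − β·SiR, per-cell ratios,
sulfapyridine ΔR in-situ calibration); TCSPC reconvolution fitting
(n-exponential decay ⊗ IRF, Poisson-weighted, reduced-χ² gatekeeping);
and flow-cytometry analysis (three-stage gating, median TMR/FRET per
condition normalized to control, Kruskal–Wallis with Dunn's post-hoc test
and Benjamini–Hochberg correction). A calibration registry ships the
published sensor constants (e.g. c₅₀ = 29 nM and r₅₀ = 30 for the NADP
sensor, c₅₀ = 130 µM at 37 °C for the NAD sensor, K₅₀ = 11.6,
K_D′ = 363 µM for lifetime readouts).

## Worked example

Fit a synthetic NADP⁺ titration (triplicates, 1% multiplicative noise)
generated from the published calibration truth, then convert a cellular
readout:

```python
import numpy as np
import fretquant as fq
from fretquant.synthetic import gen_titration

p = fq.get_calibration("nadp-25C-invitro")        # c50 29 nM, 8.9-fold range
ds = gen_titration(p, np.geomspace(1, 900, 12), noise=0.01, seed=1)
fit = fq.fit_isotherm(ds, model="analyte")
print(fit.summary())
```

```
Single-site isotherm fit (analyte axis)
  levels: 12, replicates: 3
  R_max  = 4.46374 +/- 0.0076
  R_min  = 0.504379 +/- 0.0074
  c50    = 28.5792 +/- 0.29
  fold change R_max/R_min = 8.85
  residual sum of squares = 0.0113
```

The fitted half-response (28.6 nM) and dynamic range (8.85-fold) recover the
generating truth (29 nM, 8.9-fold) to within the replicate noise. Converting
a live-cell emission ratio with the 37 °C constants:

```python
p37 = fq.get_calibration("nadp-37C-ratio")        # R_max 4.58, R_min 0.52, r50 30
fq.redox_from_ratio(2.55, p37).value              # -> 30.0  (midpoint readout)
```

i.e. a cell reading the half-response ratio has a free NADPH/NADP⁺ of
exactly r₅₀ = 30. The same objects drive the CLI
(`fretquant simulate|calibrate|quantify-ratio|quantify-flim|cytometry`).

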