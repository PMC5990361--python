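# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `fretquant`, in the spirit of a package methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sensor response model

The sensor is treated phenomenologically as a two-state switch: an open
(low-FRET) and a closed (high-FRET) conformation in analyte-dependent
equilibrium. No ternary-complex thermodynamics (effective intramolecular
ligand concentration, π-stacking energetics) is modeled; the single-site
isotherm on each readout scale is the model.

Two readout scales coexist and are deliberately kept apart in the
calibration registry:

* **Emission ratio** R = donor/acceptor. Because donor and acceptor have
  different dynamic ranges, R is hyperbolic but not affine in occupancy, so
  its half-response constants (c₅₀ on an analyte axis, r₅₀ on a
  NADPH/NADP⁺ axis) are *apparent* constants specific to the ratio scale.
* **FRET efficiency** E (from lifetimes). Normalising a single emission
  channel by the isosbestic wavelength (645 nm) gives a signal affine in
  occupancy; the corresponding half-saturation constants (K_D′, K₅₀) are
  occupancy-scale quantities. For the same sensor K₅₀ < r₅₀, and the
  package's spectral generator plus `fit_occupancy` reproduce that ordering.

Inverse maps clamp readouts beyond the calibrated band to the nearest bound
with an explicit flag; the unbounded end (e.g. R → R_max for a redox
sensor) raises by default or returns an `inf` sentinel on request. Silent
extrapolation would produce negative concentrations and is never done.

Registry notes: the published in-vitro titrations report fold changes
(8.9× NADP, 7.6× NAD) but not absolute ratio endpoints; the 25 °C registry
entries anchor R_max/R_min as fixtures consistent with those fold changes.
The r₅₀ = 30 entries at 25 °C and 37 °C are kept as independent registry
rows rather than asserting temperature invariance. FLIM E_max = 0.70 and
E_min = 0.10 are instrument-fixture values, as are the synthetic donor
lifetimes (bi-exponential 3.2/1.8 ns, 60/40 amplitudes).

## Titration fitting

Unweighted least squares on the ratio scale (replicate s.d. is roughly
proportional to signal and ratios are fitted as plotted). Starting values
are deterministic and data-driven: R endpoints from the first/last axis
tertile medians, the half-response constant from the axis point nearest the
mid-range response. Redox-axis fits conventionally fix R_max at the value
measured with a saturating free competing ligand; on clean data fixed and
free fits agree to 1% (tested). A fit whose half-response falls outside the
sampled axis is flagged `extrapolated_half`; flat data raise rather than
returning a spurious constant.

Interference screening refits each with-metabolite dataset and flags
additives shifting the half-response more than 2-fold (either direction) or
cutting the dynamic range by more than 20%. The thresholds are package
choices; a null screen on replicate synthetic datasets stays unflagged at
1% noise.

The NADPH-stock correction takes the contamination fraction f as an input
(true NADPH = (1−f)a, true NADP⁺ = b + fa); estimating f from absorbance is
out of scope.

## Kinetics

Relaxations are single exponentials with a floating plateau;
t½ = ln 2/k by definition. Pseudo-first-order labeling series fit one
k_obs per trace and take k₂ as the slope of k_obs versus substrate
concentration through a fitted intercept (the intercept absorbs any
zero-substrate relaxation). Non-monotone traces (a counter-directional step
exceeding five times the median frame-to-frame change) are flagged, not
rejected.

## Ratio imaging

Correction order is background first (scalar per channel, from a
user-specified background-ROI median), then division by the mean-normalised
flat-field: the camera offset is added after the optics vignette that the
flat-field models, so this order is the one that inverts the acquisition
(the package's own generator closure verifies recovery of a flat scene to
1e-6). Negative pixels created by subtraction are counted and carried in
metadata.

Bleed-through coefficients are slopes over signal pixels of single-label
controls (FRET vs TMR on donor-only, FRET vs SiR on acceptor-only). Raw
per-pixel regression of a Poisson channel on another Poisson channel
attenuates the slope (errors-in-variables), so pixels are selected and
binned on a 5×5-smoothed copy of the source channel — whose noise is nearly
independent of the per-pixel shot noise — and a Theil–Sen slope is taken
over the bin means, with a least-squares fallback. This keeps the estimator
robust and removes the attenuation bias (recovery within ~1% at the fixture
photon budget, tested at 2%).

Per-ROI ratios are ratios of means (robust to low-count pixels), never
means of pixel ratios. ROIs with non-positive mean corrected FRET are
censored rows, not NaN propagation. In-situ calibration uses the per-cell
sulfapyridine ratio change ΔR = R_SPY/R_basal and R = R_max/ΔR, clamping
ΔR below 1 (a sensor cannot open beyond fully open) and flagging such
cells. No photobleaching correction and no registration are applied; masks
are assumed constant across a time series.

## TCSPC reconvolution

Expected counts are the discrete linear convolution of the
(background-subtracted, fractionally shifted, unit-area) IRF with
Σαᵢ·exp(−t/τᵢ), plus a constant decay background. The default grid is 16 ps
bins over a 50 ns window (20 MHz repetition); the synthetic IRF is Gaussian
with 250 ps FWHM (measured IRF histograms are accepted as input). IRF
shifts beyond a quarter window indicate a grid mismatch and raise.

Fitting uses variable projection: the optimizer searches the lifetimes (and
optionally the IRF shift); amplitudes and decay background enter linearly
and are solved by non-negative least squares at every step. Initialisation
is a log-spaced lifetime ladder, making the fit deterministic for given
data. Weights begin as 1/max(count, 1) and are then iteratively reweighted
from the fitted model (floored at one count): weighting by observed counts
alone systematically biases lifetimes low through the sparse histogram
tail, and the reweighted scheme removes that bias while keeping the
least-squares framework (maximum-likelihood fitting is deliberately out of
scope).

The reduced χ² is computed over bins with expected count ≥ 1, with degrees
of freedom equal to that bin count minus the free parameters. Restricting
the sum to the same bins as the dof keeps E[χ²_red] ≈ 1 for a correctly
specified model; including the sub-one-photon tail in the sum but not the
dof would structurally inflate it. Fits with χ²_red ≥ 1.2 are returned
flagged `rejected` and refuse downstream quantification unless explicitly
overridden. The IRF background term exists in the model but is held at zero
during fitting (synthetic IRFs are background-free; measured IRFs can be
pre-corrected through the same parameter).

FRET efficiencies use amplitude-weighted mean lifetimes; ⟨τ_DA⟩ exceeding
⟨τ_D⟩ by up to 2% (noise) clamps to E = 0 with a flag, larger excesses are
censored. One donor-only reference is fitted per batch and shared across
the batch's cells; E_min comes from each cell's sulfapyridine decay, E_max
from the registry.

## Cytometry

Gating is three sequential threshold gates with data-driven defaults:
debris below 0.25× the median of either scatter channel (optionally with
absolute floors), doublets above 1.5× the median SSC-W, labeled events
above 0.10× the median TMR and SiR — or absolute positivity thresholds at
the 99.5th percentile of an unlabeled reference when one is supplied. Each
threshold is iterated to a fixed point of the kept population, which makes
gating exactly idempotent. The published gates are drawn graphically, not
numerically; these rules are declared defaults.

Summaries are per-replicate medians of the event-level TMR/FRET ratio,
averaged across replicates and normalised to the control mean (control = 1
by construction). Statistical testing runs on gated event-level ratios
(replicate-level medians at n = 3 would be underpowered): Kruskal–Wallis
with mid-rank tie correction, Dunn's z against control, two-tailed normal
p-values, Benjamini–Hochberg adjustment at α = 0.05. An exact-permutation
Kruskal–Wallis p-value is available for small pooled samples and matches
exhaustive enumeration. Under the global null the per-comparison rejection
rate of the Dunn+BH screen — the quantity the FDR procedure controls —
stays below α (tested over 200 seeded replicates); the family-wise
any-rejection probability of any exactly calibrated test is itself ≈ α and
is not a meaningful acceptance quantity. Cytometer ratios are relative
(instrument R_min/c₅₀ cannot be calibrated), so converted concentrations
are labeled estimates only.

## Synthetic data

Noise families follow detector physics: mean-one lognormal multiplicative
noise for plate-reader ratios (default 1%, technical triplicates), Poisson
photon noise for images and TCSPC histograms, Gaussian noise for kinetic
traces, lognormal clouds for cytometry events. Every generator is a
bit-reproducible function of its arguments and a seed.

Scenes place non-overlapping ellipse cells with per-cell ground truth; the
donor/FRET split of a per-cell brightness makes TMR/FRET equal the true
ratio exactly before mixing (α, β), vignetting, background and Poisson
sampling. Spectra mix open/closed endmember bands constructed to peak at
577/667 nm and intersect exactly at 645 nm (their precise shape is
irrelevant beyond those constraints). Cytometry events include debris (low
scatter), doublets (doubled SSC-W and fluorescence) and unlabeled
(background fluorescence) subpopulations at configurable fractions
(defaults 5/8/10%), with condition effects as fold-shifts of the ratio
center.

What the generators do **not** emulate: realistic cell morphology and
texture, the microscope PSF, detector afterpulsing and pile-up, spectral
overlap beyond the two mixing coefficients, autofluorescence gradients, or
biological cell-to-cell covariance structure. Passing closures therefore
demonstrate correctness of the estimators under the stated statistical
assumptions, not robustness to every artifact of real acquisitions.

## Problem sizes and determinism

Default analysis problem sizes were chosen to match the acquisition regimes
the pipeline targets: 12-point titrations in triplicate, 192×192-pixel
scenes with ~10 cells at a ~2000-count photon budget, 10⁶-count decay
histograms (batches of ten cells, one donor reference per batch), and
cytometry runs of a few thousand events per replicate in triplicate.
Noiseless fit closures use 10⁸-count quantized histograms so that integer
rounding, not the estimator, is the limiting error. All stochastic tests
and the acceptance script derive every random stream from an explicit seed.

## Known limitations

* Lifetime fits with more than three components are not exposed; deeply
  overlapping lifetime triples remain statistically degenerate even at 10⁶
  counts (the amplitude-weighted mean is what the quantification consumes,
  and it is well determined).
* The ratio→analyte inverses amplify readout noise near the calibration
  bounds; estimates there arrive censored rather than precise.
* FCS binary parsing, pixel-wise FLIM maps, phasor analysis, image
  registration and automated segmentation are out of scope.
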