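# Methods

## Scope and design

`nanoxrf` reconstructs, as seedable software, the measurement chain of a
scanning nano-XRF tissue experiment: phantom → expected spectra → Poisson
acquisition → per-pixel deconvolution → data mining → calibrated
quantification. The guiding constraint is that every stage downstream of
the phantom must be blind to the ground truth: fits see only counts,
calibration sees only the simulated reference measurement, and recovery is
judged afterwards against the phantom. Where the original experimental
practice relies on full Monte Carlo photon transport for quantification,
this package substitutes an analytic fundamental-parameter expectation with
Poisson sampling: it preserves the same intensity ↔ concentration contract
and is deterministic in expectation, which makes oracle tests possible at
desk scale.

## Tissue phantom

The phantom emulates a 2 µm paraffin tissue section at 50 nm pixels
(default field 128×128 px = 6.4×6.4 µm; a 20 nm "nucleus detail" mode
mimics zoomed scans). Compartments and their elemental signatures:

- **Cells** (placed non-overlapping until a target area fraction drawn in
  30–60% is reached; radius 1.8 µm ± 25% jitter): P-rich membrane
  (150 nm rim) and nucleus (P weights membrane:nucleus:cytoplasm:stroma =
  5:4:2:1), Zn-rich nucleoli (Zn 10:4:1:0.5 for
  nucleolus:nucleus:cytoplasm:stroma, 2–4 nucleoli of ~180 nm kept
  strictly inside the nucleus matrix).
- **Stroma**: S-enriched (stroma:cell = 1.5:1).
- **Pt strings**: correlated random-walk paths 2–4 px wide through the
  stroma, 5× the stromal Pt level; Br weights are proportional to Pt's.
  The extracellular (stroma+string) to cellular Pt weight ratio is
  rescaled so the area-weighted contrast equals exactly 2.0 before noise.
- **Fe** is drawn as a compartment-independent field (it tracks no tissue
  structure).

Within-compartment heterogeneity is multiplicative mean-one lognormal with
CV 0.2, truncated at ±2σ of the underlying normal. The truncation is a
deliberate bound: P and S sit at wt% levels, and an untruncated lognormal
tail can push a single pixel's summed mass fraction toward the organic
matrix budget (the generator guarantees Σc < 0.2 everywhere). After noise,
each element's map is renormalized so its area mean equals the target
exactly (relative error < 1e-12), which makes map-mean recovery tests
sharp.

Group presets carry the measured cohort composition (map means for
P/S/Zn/Pt per treatment protocol, common trace levels Ca 100 ppm, Mn
5 ppm, Fe 50 ppm, Br 10 ppm). Untreated tissue has true Pt ≡ 0 — any
quantified Pt there is spectral noise, which is exactly what the
below-detection-limit check needs. For cohort simulations,
`TissueProfile.sample_group` draws each sample's map means from the group
mean ± between-sample SD (truncated at 10% of the mean): group SDs in a
cohort table measure tumor-to-tumor variability, not counting noise, and
without this draw a simulated cohort would show absurdly small
between-sample spread and spurious "significant" group differences.

What the phantom does **not** emulate: organelle-scale texture beyond the
compartments above, elemental gradients with depth, paraffin/substrate
contributions, or spatially correlated noise. Passing tests show the
pipeline recovers what it was pointed at under realistic counting
statistics — not that real tissue is this simple.

## Forward spectral model

Per-line detected counts per (wt fraction · s):
`S_line = Φ·(Ω/4π)·ε(E)·k_e(E₀)·rel_line·ρt·A(E)`.

- Φ = 2×10¹¹ ph/s, E₀ = 17.5 keV, beam normal to the section; detector at
  77° to the beam (the 13° off-90° geometry), so the exit path uses
  sin ψ_out = cos 77°.
- Ω/4π = 0.04 (both three-element SDD arrays merged into one effective
  detector; only the product of flux and solid angle matters). This value
  was chosen once so Zn at its measured tissue level yields ~10³ counts
  per 0.1 s pixel — a realistic counting-statistics regime.
- k_e lumps photoelectric cross-section at E₀, shell fraction and
  fluorescence yield; values are embedded coarse transcriptions from
  standard tables. Their absolute accuracy is not load-bearing because
  calibration and quantification round-trip through the same model — only
  count-level realism matters.
- Matrix attenuation uses a two-term law µ(E) = 4500·E⁻³ + 0.18 cm²/g
  (soft-tissue-like); the detector window is 25 µm Be with the analogous
  law. Self-absorption uses the thin-slab factor A; for the 2 µm section
  A ≈ 1 above 5 keV but ≈ 0.8 for P Kα, and for the 100 µm reference slab
  A(P Kα) ≈ 0.04 — the reason calibration transfer matters (below).
- Detector response: Gaussian lines integrated over 10 eV channels (2048
  channels), FWHM² = (130 eV)² + 2.46·(E − 5.9 keV) in eV — a typical
  silicon-drift detector. K series for Z ≤ 35, Lα/Lβ/Lγ for Pt, branching
  ratios group-normalized.
- Background: exponential-decay + pedestal continuum scaled by beam ×
  areal density, plus Rayleigh (at E₀) and Compton (at the closed-form
  scattered energy for the detector angle, doubled width for Doppler
  broadening) Gaussian peaks. Continuum fidelity is deliberately modest;
  nothing downstream depends on its exact shape. Beam bandwidth, escape
  peaks and pile-up are out of scope.

Acquisition is an independent Poisson draw per channel
(`numpy.random.default_rng(seed)` everywhere; one integer reproduces a
whole run).

## Spectrum fitting

Two tiers, mirroring how map-scale XRF fitting is done in practice:

1. **Sum spectrum** (high statistics): nonlinear refinement of the two
   shared shape parameters (FWHM_ref, Fano slope) by variable projection —
   amplitudes are profiled out by the inner linear solve. Energy
   calibration (gain/offset) is taken from metadata.
2. **Per pixel** (fixed shapes): weighted linear least squares over element
   line-group amplitudes plus continuum columns, vectorized over pixels.

Numerical choices that matter:

- **Background**: default is a Chebyshev polynomial basis of degree 12
  inside the weighted solve. Degree 12 is the smallest that leaves the
  500 s reference continuum misfit below Poisson noise (a cubic leaves
  >200σ residuals); for 0.1 s pixels any degree ≥ 3 is statistically
  indistinguishable, so one default serves both. SNIP (LLS transform,
  decreasing clipping windows, never exceeding the input) is available as
  an alternative background estimator.
- **Weights**: iteratively reweighted (2 reweights) starting from
  observed-count weights with a variance floor of 1, then from
  model-predicted counts. Pure observed-count weighting down-weights
  upward Poisson fluctuations and biases low-count amplitudes low — on
  0.1 s tissue pixels the Pt group came out −5% and Br −19% before
  reweighting, <0.4% after.
- **Negative amplitudes** are clipped to zero and flagged (concentrations
  are physical). At the few-count level this clipping makes map means
  positively biased — e.g. Mn at 5 ppm (~4 expected counts/pixel) can show
  tens of percent of positive bias. That is a property of any
  non-negative estimator in the deep-Poisson regime, and it is why
  uncertainty calibration is asserted only for groups with ≳20 expected
  counts.
- **Uncertainties** come from the covariance of the final weighted solve
  (background columns marginalized); z-scores over Poisson replicates are
  centered with SD in [0.8, 1.2] and reduced χ² ≈ 1.
- **I_b convention**: the background under a peak is the fitted continuum
  integrated over ±1 FWHM around the element's principal line
  (configurable); this is the I_b entering the detection-limit formula.

## Data mining

k-means is a compact Lloyd implementation with k-means++ seeding, best of
`n_init` restarts, lowest-index tie-breaking and an asserted-monotone
inertia trace (scikit-learn's KMeans is used as an independent cross-check
in the tests, and exhaustive partition enumeration as the small-n oracle).
PCA delegates to scikit-learn with a sign convention (largest-magnitude
loading positive). Features default to z-scored columns — without scaling,
wt%-level P and S would drown the trace elements.

One genuinely open design point: with the compartment weights above, the
inertia-optimal 3-partition of (P, S, Zn, Pt) features separates
nucleus+membrane from cytoplasm+stroma from strings — the within-cell
contrast dominates the cytoplasm/stroma one. This matches what 3-cluster
maps of real tissue show (a Pt-bearing cluster plus nucleus and cytoplasm
clusters); a clean {cell, stroma, string} recovery needs k = 4, after
which majority-label mapping agrees with ground truth at ~0.91. The tests
assert both behaviors rather than forcing k = 3 to do what it provably
cannot.

## Quantification and detection limits

Calibration measures S_e = I_e/(C_e·t) on the simulated reference standard
(embedded certified values of a bovine-liver standard: P 1.175%, S 0.749%,
Ca 131 ppm, Mn 10.46 ppm, Fe 197.9 ppm, Zn 181.1 ppm) and transfers it to
the tissue geometry by the ratio of analytic (ρt · self-absorption)
factors. The transfer is the self-absorption correction for low-energy
lines: without it, P would be wrong by a factor ~19 between the 100 µm
slab and the 2 µm section. Pt and Br have no certified reference value;
their sensitivities come from the forward model directly — the analytic
counterpart of a simulation-derived calibration. Concentrations are then
c = I/(S_e·dwell), linear by construction.

Detection limits use DL_i = 3√I_b·C_i/I_i at the calibration live time,
extrapolated to the 0.1 s scan dwell as t^(−1/2) (both I_b and I_i grow
linearly in t). For uncertified elements the identity C_i/I_i = 1/(S_e·t)
gives DL = 3√I_b/(S_e·dwell) with I_b taken from the mean fitted per-pixel
tissue background. An absolute-mass form multiplies by the illuminated
volume (beam footprint × thickness × density). The package computes DLs
for its own simulated instrument; they are not comparable to any
particular beamline's published values, which depend on the real detector
response.

Group summaries report mean ± SD of per-sample map means, with elements
whose group mean falls below the DL flagged and reported without a
numeric value. The treatment comparison uses Welch's unequal-variance
t-test with Satterthwaite degrees of freedom (the conservative default
when group variances differ several-fold, as they do for Pt).

## Problem sizes and runtime

Defaults keep a full phantom → quantification run at ~15–25 s on one CPU:
128×128 pixels × 2048 channels, 0.1 s dwell, 500 s reference. The test
suite uses 32–64 px maps for unit-level checks and reserves 128×128 for
the end-to-end recovery tests; the cohort driver uses 64×64 per sample.
These sizes were chosen so the complete chain stays interactive while the
per-pixel statistics remain those of a real 0.1 s dwell.

## Known limitations

- The forward model and the quantification share the same attenuation and
  production constants, so constant errors cancel; against real data the
  calibration-transfer accuracy would be limited by how well µ(E) and the
  detector response are known.
- No escape/sum peaks, no beam-energy bandwidth, no detector tailing;
  spectra are cleaner than real SDD spectra at the same statistics.
- Clip-at-zero bias for sub-10-count elements (see above).
- The phantom's compartments are piecewise-stationary; real tissue
  exhibits gradients and correlated texture the segmentation tests never
  see.
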