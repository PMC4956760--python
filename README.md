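# nanoxrf

A synthetic scanning nano-XRF (X-ray fluorescence) imaging pipeline for
studying how the chemotherapy drug cisplatin distributes through tumor
tissue at sub-cellular resolution, using platinum as its elemental tracer.

Synchrotron nano-probes scan a focused 50×50 nm X-ray beam (17.5 keV,
~2×10¹¹ ph/s) across a 2 µm tissue section, recording a full
energy-dispersive spectrum per pixel at 0.1 s dwell. Deconvolving those
spectra yields elemental maps — P outlining cell membranes and nuclei, Zn
marking nucleoli, S enriched in the stroma — against which the Pt
distribution can be read: does the drug enter the cancer cells, or stay in
the connective tissue between them? Because raw beamline data of this kind
are rarely deposited, `nanoxrf` provides the entire measurement chain as
tested, seedable software: tissue phantoms with known ground truth, an
analytic fundamental-parameter forward model of the spectrometer, per-pixel
spectral fitting, k-means/PCA map mining, and calibrated quantification
with detection limits. Every downstream claim can therefore be checked
against the phantom it was generated from.

## The model

**Forward model.** The detected counts of element *e*'s line group per unit
concentration and time (its *sensitivity*) are

```
S_e = Φ · (Ω/4π) · ε(E_line) · k_e(E₀) · ρt · A_e
A_e = (1 − e^(−χρt)) / (χρt),   χ = µ(E₀)/sin ψ_in + µ(E_line)/sin ψ_out
```

with beam flux Φ, detector solid-angle fraction Ω/4π, window transmission
ε, fluorescence-production factor k_e at the excitation energy E₀, areal
density ρt and the thin-slab self-absorption factor A_e. Lines are spread
as Gaussians with FWHM²(E) = FWHM²_ref + c_Fano·(E − E_ref); a smooth
continuum plus Rayleigh and Compton scatter peaks (E′ = E₀ / (1 +
(E₀/511 keV)(1 − cos θ))) complete the expectation, and acquisition is a
per-channel Poisson draw.

**Inverse chain.** Per-pixel spectra are fitted by iteratively reweighted
least squares over element line groups (branching ratios tied, so the
Pt Lα / Zn Kβ overlap at 9.4–9.6 keV stays identifiable) with a polynomial
continuum; detector shape parameters are refined once on the map's sum
spectrum. Sensitivities are calibrated from a simulated 500 s measurement
of a bovine-liver reference standard (S_e = I_e / (C_e·t), transferred
from the 100 µm slab to the 2 µm section geometry); elements without a
certified value (Pt, Br) use the forward model's sensitivity, the
counterpart of a simulation-aided calibration. Detection limits follow the
3-s.d. criterion

```
DL_i = 3·√I_b · C_i / I_i ,    DL(t₂) = DL(t₁)·√(t₁/t₂)
```

## Worked example

```python
from nanoxrf.pipeline import run_pipeline

res = run_pipeline("normothermic", shape=(128, 128), seed=7)
print(f"Pt map mean: {res.map_mean('Pt')*100:.4f} wt%")
print(f"stroma:cell Pt ratio: {res.stroma_cell_pt_ratio:.2f}")
print(f"r(Pt,Br) = {res.extras['correlations'].loc['Pt','Br']:.3f}")
```

prints (seed 7):

```
Pt map mean: 0.0180 wt%
stroma:cell Pt ratio: 2.00
r(Pt,Br) = 0.886
```

The phantom was built with a map-mean Pt of 0.018 wt% and twice as much Pt
outside the cells as inside — the pipeline recovers both through the full
simulate → fit → calibrate → quantify chain. The Pt–Br correlation is the
strongest off-diagonal Pt entry, reflecting the halide that co-locates
with the drug, and k-means puts the Pt-rich cluster entirely outside the
cells.

The numbered drivers under `analysis/` run the same stages as a narrative:
`01_build_phantom.py` (geometry and ground truth), `02_simulate_and_fit.py`
(scan simulation and per-pixel deconvolution, with a fit-bias audit),
`03_mine_maps.py` (clustering, PCA, correlations), `04_quantify_groups.py`
(a 2+5+7-sample cohort with tumor-to-tumor variability, detection-limit
flagging and Welch's test — printing, e.g., `untreated Pt below DL: True`
and `Welch Pt hyper vs normo: p = 0.888 -> no significant difference`).
Summaries land in `results/`, bulky maps in `scratch/`. A `nanoxrf` CLI
(`phantom`, `simulate`, `fit`, `mine`, `quantify`, `report`, `pipeline`)
exposes the same stages with `--config/--seed/--out` and a reproducibility
log per run.

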