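# Methods

`cardioswi` implements the TE-averaged susceptibility-weighted imaging (SWI)
chain for detecting intramyocardial hemorrhage (IMH) in multi-echo
gradient-echo cardiac MR, together with a digital left-ventricle phantom that
supplies exact ground truth for every stage. This note records the models,
the numerical choices, and what the phantom does and does not emulate.

## Signal model and phantom

Each phantom pixel follows the offset-free mono-exponential gradient-echo
model

    S(TE) = ρ · exp(−TE/T2*) · exp(i·(2π·Δf·TE + φ_focal·w(x,y)))

with proton density ρ (arbitrary units), effective transverse relaxation
time T2* (ms), global off-resonance Δf (Hz, a spatially smooth phase source),
and an extra focal phase φ_focal (radians) applied only inside the lesion
(w = 1 there, 0 elsewhere). Negative focal phase models the susceptibility
shift of paramagnetic blood-breakdown products.

Default study conditions:

| parameter | default | rationale |
|---|---|---|
| grid | 192 × 192, 1.5 mm pixels | method-scale grid; the filter is defined in k-space samples, not mm |
| LV annulus | radii 18–27 px (≈ 27–40 mm) | adult short-axis mid-ventricle |
| lesion | radius 4 px (≈ 12 mm Ø), inferior wall | typical reperfusion-hemorrhage size |
| myocardium | ρ=1, T2*=34.1 ms | healthy segmental mean |
| lesion tissue | ρ=1, T2*=16.2 ms, φ_focal=−1 rad | hemorrhagic segmental mean; φ_focal is a free parameter (no in-vivo value is available), set to mid-ramp of the mask |
| blood pool | ρ=0.3, T2*=80 ms | qualitative stand-in for dark-blood preparation |
| echoes | 12, linspace(2.4, 15.5) ms | protocol echo table; the stated endpoints imply 1.19 ms spacing (the nominal 1.2 ms spacing and the 15.5 ms endpoint are mutually inconsistent by 0.1 ms; the endpoints win) |
| coils | 4 Gaussian-falloff profiles, SOS-normalized to 1 | enough to exercise sum-of-squares combination; geometry is irrelevant to the method |
| noise | σ = 0.02 per complex channel per coil | first-echo myocardial magnitude SNR ≈ 30 after coil combination, a realistic segmented-GRE operating point |

K-space is the centered orthonormal 2-D FFT of the coil-weighted image plus
i.i.d. circular complex Gaussian noise; one FFT convention (DC centered,
`norm="ortho"`) is used everywhere, so the noiseless simulate→reconstruct
roundtrip is exact to machine precision and Parseval holds without scale
factors.

The lesion's focal phase is a spatially compact constant offset, not a
dipole field: it is the minimal model that survives homodyne filtering and
supports a closed-form contrast oracle. The phantom has no cardiac motion,
no flow phase, no B0 inhomogeneity beyond a constant, and no Rician spatial
correlation — passing tests demonstrate correctness of the reconstruction
and analysis operators, not clinical detectability in vivo.

## Reconstruction and homodyne phase filtering

Every echo and coil is reconstructed independently by centered inverse FFT.
Magnitude is combined across coils by sum-of-squares. Phase is high-pass
filtered by complex division: the full-resolution image is divided by its
low-pass-filtered self, where the low-pass is a radial squared-Hanning
window of N = 64 k-space samples diameter,

    W(r) = [0.5·(1 + cos(2πr/(N−1)))]²  for r ≤ (N−1)/2, else 0.

W(0) = 1 (a low-pass must pass DC; the descending half of the squared
Hanning is the standard homodyne construction) and W decreases monotonically
to zero at radius ≈ 32 samples. Per-coil complex ratios are combined by a
magnitude²-weighted complex sum — phase-reference-free and standard for
phased arrays — and the phase of the combined ratio is the HPF phase.
Pixels where any coil's LPF magnitude falls below 1e−6 of the stack peak are
flagged invalid, carried as a validity plane, and excluded from all ROI
statistics; invalid pixels inherit mask = 1 downstream so masked regions
cannot fabricate lesions.

How much focal phase survives the filter depends on the lesion size relative
to the filter's image-domain kernel (≈ 2.8·grid/N pixels FWHM). A compact
lesion (extent ≪ grid/N) keeps essentially all of its phase offset (91% at
radius 2 on a 256 grid); the default 4-pixel-radius lesion on the 192 grid
keeps about half. This attenuation only scales the SWI contrast gain — all
ordering properties (SWI > magnitude, 6 > 3 multiplies) are preserved — and
is why phantom contrast-gain numbers are illustrative rather than
reproductions of patient values.

## Phase mask and SWI

    mask(φ) = (π + φ)/π  for −π < φ < 0;  1 otherwise
    SWI = |I| · maskⁿ

applied per echo with that echo's own HPF phase, on the coil-combined
magnitude (one combined mask rather than per-coil masks, avoiding coil-phase
noise amplification). Default n = 6 multiplications (deeper suppression of
negative-phase tissue than n = 3, at the cost of amplified phase noise).
n = 0 is the identity. On a noiseless phantom the lesion-vs-myocardium SWI
contrast equals the closed form 1 − (S_lesion/S_myo)·mask(φ)ⁿ, which the
test suite checks to 1e−6.

## TE-averaging

The nTE longest-echo images are averaged arithmetically (a mean, not a sum:
it keeps the intensity scale comparable across nTE; contrast and SDNR are
invariant either way). A 12-echo series yields 11 distinct multi-echo
averages; nTE = 1 is the longest-TE image unchanged. Averaging trades
contrast (diluted by the weakly-weighted short echoes) against noise (STD of
the mean falls as 1/√nTE). With the default tissue T2* values the magnitude
SDNR-vs-nTE curve rises to an interior maximum (nTE ≈ 10) before falling —
the averaging gain initially outweighs contrast dilution. Under the
TE-independent focal-phase model, the SWI signal difference is largest at
short TEs (the mask suppresses the lesion equally at every echo while
myocardium decays), so the SWI curves keep rising to nTE = 12; a TE-growing
susceptibility phase would be needed to reproduce an interior SWI optimum,
and is deliberately outside this phantom's model.

Grayscale inversion (clip to a window, map v → (high−v)/(high−low)) renders
hemorrhage hyperintense for display; it is flagged display-only and never
enters metrics. The default window is [0, 99th percentile].

## T2* estimation

ROI-mean decay curves (not pixelwise maps) are fitted with

    S(TE) = So·exp(−TE/T2*) + C

by bounded trust-region least squares (T2* ∈ (0.1, 500] ms), initialized
with C₀ = min S, So₀ = max S − C₀, and T2*₀ from a log-linear fit of the
first half of echoes after offset subtraction. The offset C absorbs the
magnitude noise floor, so no Rician likelihood is used. Unidentifiable fits
(zero amplitude, bound-pinned T2*, optimizer failure) are returned with
`converged = False`, never raised.

Conditioning caveat: over a 2.4–15.5 ms echo range, TE_max/T2* is only 0.45
for normal myocardium, and the three-parameter fit amplifies relative curve
noise by roughly 30×. Applying "SNR 20" noise directly to a 12-point curve
makes the estimator useless (an exact global-minimum oracle shows a median
estimate of ~45 ms for a true 34 ms) — which is precisely why the procedure
fits ROI means: averaging ~100 pixels brings the median error to ~1–3%.
The replicate tests simulate that measurement chain (per-pixel complex noise
at first-echo SNR 20, magnitude, 100-pixel ROI mean). The same amplification
explains the tens-of-percent sector-to-sector scatter of segmental T2* on
noisy phantoms; the homogeneity test bounds the spread at 35% with the group
mean within 10% of truth, values derived from the propagation factor.

Sectors follow the per-slice AHA convention: the annulus is partitioned
about its centroid into 6 equal angular sectors (basal, mid) or 4 (apical),
numbered counterclockwise from the RV-insertion reference angle; the apex
cap is not modeled.

## Metrics

Contrast = (S1−S2)/S1 and SDNR = (S1−S2)/STD, with S1 the adjacent
(remote) myocardium mean, S2 the lesion mean, and STD the raw standard
deviation of magnitude values in a signal-free ROI — uncorrected for
Rayleigh statistics, mirroring the operational definition. The remote ROI
excludes a 2-pixel guard ring around the lesion to avoid partial-volume
contamination. Threshold volumetry implements the half-maximum rule over
the LV mask with enclosed hypointense cores added (a 4-connected
below-threshold component counts as enclosed only if it reaches neither the
array border nor any out-of-mask pixel); hypointense-lesion volumetry takes
an explicit numeric threshold in place of visual thresholding. Volumes are
reported as a percentage of the LV myocardial mask.

## Problem sizes

Test and acceptance runs use the default 192² grid, 12 echoes, 4 coils, and
one noisy realization per property check (the SDNR-peak property was
verified stable across 12 seeds before freezing); the replicate suite uses
200 curves of 100 pixels. The full suite runs in well under a minute on one
CPU.

## Known limitations

- The focal lesion phase is TE-independent and the phantom contrast gain
  depends on it; absolute contrast/SDNR values are not comparisons against
  patient data.
- Single-slice, static, noise-only degradation; no motion, flow, or
  dark-blood preparation physics.
- No phase unwrapping: upstream phase must already be in (−π, π] (true by
  construction here).
- Sector T2* at realistic SNR is dominated by fit-conditioning noise, not by
  tissue differences smaller than ~20%.
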