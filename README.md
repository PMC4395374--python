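# cardioswi

TE-averaged susceptibility-weighted imaging (SWI) for intramyocardial
hemorrhage (IMH) in multi-echo gradient-echo cardiac MR.

After reperfused myocardial infarction, hemorrhage deposits paramagnetic
blood products in the infarct core. These shorten T2* and shift the local
resonance, leaving a dark, negative-phase lesion on gradient-echo images.
`cardioswi` implements the full reconstruction and analysis chain that turns
a 12-echo multi-coil acquisition into hemorrhage-weighted images and ROI
measurements, and a digital short-axis left-ventricle phantom that provides
exact ground truth for every stage. It is intended for MR-physics and
image-reconstruction researchers working on myocardial tissue
characterization.

## Method

For each echo TE and coil, the complex image `I` is reconstructed by
centered inverse 2-D FFT. Magnitude is combined across coils by
sum-of-squares. Background phase is removed by homodyne filtering — divide
`I` by its low-pass-filtered self (radial squared-Hanning window, N = 64
k-space samples) and keep the angle φ. The phase mask emphasizes negative
phase:

    mask(φ) = (π + φ)/π   for −π < φ < 0
    mask(φ) = 1           otherwise

    SWI = |I| · maskⁿ     (n = 3 or 6 mask multiplications)

To trade contrast for SNR, the nTE longest-echo images are averaged
(nTE = 1 … 12; a 12-echo series gives 11 distinct multi-echo averages).
ROI analysis uses

    contrast = (S1 − S2)/S1        SDNR = (S1 − S2)/STD

with S1 the adjacent-myocardium mean, S2 the lesion mean, and STD the raw
standard deviation in a signal-free noise ROI. ROI-mean decay curves are
fitted with `S(TE) = So·exp(−TE/T2*) + C` per AHA-style angular sector, and
lesion volumes use a 50%-of-maximum threshold with enclosed hypointense
cores included. See `docs/methods.md` for assumptions, defaults, and
numerical details.

## Worked example

```python
import numpy as np
from cardioswi import *
from cardioswi.phantom import phantom_rois

spec = PhantomSpec(seed=42)                      # default study conditions
k = simulate_kspace(spec)                        # multi-coil 12-echo k-space
es = reconstruct(k)
mag = sos_magnitude(es)                          # coil-combined magnitude
phase, valid = hpf_phase(es)                     # homodyne-filtered phase
swi6 = swi_series(mag, phase, n_multiplies=6, valid=valid)

rois = phantom_rois(spec)
rep = sweep_report(mag, {"swi6": swi6}, rois, es.echo_times,
                   np.broadcast_to(valid, mag.shape))
for src in ("magnitude", "swi6"):
    r1 = rep[(rep.source == src) & (rep.n_te == 1)].iloc[0]
    r9 = rep[(rep.source == src) & (rep.n_te == 9)].iloc[0]
    print(f"{src:9s} nTE=1: contrast={r1.contrast:.3f} SDNR={r1.sdnr:5.1f}   "
          f"nTE=9: contrast={r9.contrast:.3f} SDNR={r9.sdnr:5.1f}")

fit = fit_t2star(DecayCurve(es.echo_times,
                            mag[:, rois["lesion"]].mean(axis=1)))
print(f"lesion ROI T2* = {fit.t2_star:.1f} ms (truth 16.2)")
```

prints

```
magnitude nTE=1: contrast=0.388 SDNR= 17.3   nTE=9: contrast=0.282 SDNR= 47.5
swi6      nTE=1: contrast=0.830 SDNR= 19.5   nTE=9: contrast=0.774 SDNR= 64.7
lesion ROI T2* = 16.3 ms (truth 16.2)
```

Reading: phase masking roughly doubles lesion contrast at every echo
(0.83 vs 0.39 at the longest TE); averaging the 9 longest echoes dilutes
contrast slightly but nearly triples SDNR for both reconstructions; and the
fitted lesion T2* recovers the simulated hemorrhagic value from the noisy
magnitude images.

The same chain is available from the shell:

```sh
cardioswi run --config config.yaml --out out/ --seed 42
```

which writes magnitude/phase/SWI/TE-averaged NIfTI stacks, the
contrast/SDNR sweep table, per-sector T2* fits, ROI labels, and a
provenance record.

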