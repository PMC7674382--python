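# nmmt — quantitative & transient magnetization transfer for neuromelanin-MRI

Neuromelanin-sensitive MRI shows the locus coeruleus (LC) and substantia
nigra (SN) as hyperintensities after off-resonance saturation, but the
biophysical source of that contrast is contested (short free-water T1?
short bound-pool T1? macromolecular content?).  `nmmt` implements the full
quantitative analysis chain used to attribute the LC contrast to a reduced
macromolecular pool size ratio *f*, for researchers working on brainstem
qMT, relaxometry and NM-MRI methods:

* **Two-pool steady-state qMT.**  The z-spectrum (normalized signal
  MT<sub>norm</sub> over saturation amplitude ω<sub>1,CWPE</sub> and offset
  Δ) follows the algebraic steady state of the coupled free/restricted
  longitudinal system,

  M<sub>z</sub><sup>f</sup> = [R<sub>1r</sub>·k<sub>fr</sub>/R<sub>1f</sub> + W<sub>r</sub> + R<sub>1r</sub> + k<sub>rf</sub>] /
  [(k<sub>fr</sub>/R<sub>1f</sub>)(R<sub>1r</sub> + W<sub>r</sub>) + (1 + W<sub>f</sub>/R<sub>1f</sub>)(W<sub>r</sub> + R<sub>1r</sub> + k<sub>rf</sub>)],

  with W<sub>r</sub> = π·ω₁²·G(Δ, T<sub>2r</sub>) (super-Lorentzian
  lineshape), W<sub>f</sub> = (ω₁/2πΔ)²/T<sub>2f</sub>, and
  f = k<sub>fr</sub>/k<sub>rf</sub>.  R<sub>1r</sub> is fixed at 1 s⁻¹ and
  R<sub>1f</sub> is re-derived at every optimizer iterate so that the slow
  recovery eigenvalue of the exchange system equals the measured 1/T₁.
* **Transient MT.**  After a short saturation the free-pool fractional
  saturation is an exact bi-exponential
  s<sub>f</sub>(t) = a₁e^(−λ₁t) + a₂e^(−λ₂t) (eigen-decomposition of the
  2×2 exchange matrix), with sensitivity sweeps and the
  inversion-vs-saturation contrast comparison.
* **Relaxometry.**  Voxelwise MTR, mono-exponential T2\* (log-linear and
  NLS), MP2RAGE-style T1 with a T1–B1 dictionary, phantom heating-drift
  correction.
* **ROI statistics.**  Phantom concentration/model OLS with post-hoc
  contrasts; young-vs-old models per (ROI, scan) with an average-edge-
  strength (AES) motion confound and Benjamini–Hochberg FDR.
* **Synthetic data.**  Generators for every input (layered melanin/agar
  phantom, z-spectra, transient cohorts, two-group ROI datasets) with
  Rician noise, fixed seeds and serialized ground truth.

## Worked example

Fit the constrained two-pool model to a noiseless LC z-spectrum generated
from a representative single-subject parameter set:

```python
from nmmt import synth, fit_z_spectrum
from nmmt.presets import LC_SUBJECT1

spec, truth = synth.make_z_spectra(LC_SUBJECT1.params(), roi_label="LC")
fit = fit_z_spectrum(spec)
print(f"f    = {fit.estimates['f'] * 100:.2f} %")
print(f"krf  = {fit.estimates['krf']:.2f} Hz")
print(f"T2f  = {fit.estimates['T2f'] * 1e3:.2f} ms")
print(f"T2r  = {fit.estimates['T2r'] * 1e6:.2f} us")
```

prints

```
f    = 4.93 %
krf  = 7.03 Hz
T2f  = 154.46 ms
T2r  = 10.75 us
```

i.e. the fit recovers the generative LC values exactly: a macromolecular
pool of ~5% exchanging at ~7 Hz, with free/restricted transverse times of
~154 ms and ~11 μs.  The same roundtrip for the ROI means gives the
ordering f(LC) 5.15% < f(Pons) 10.53% < f(SN) 14.54% — the LC
hyperintensity goes with a *lower* macromolecular fraction.

The four numbered scripts under `analysis/` run the complete narratives
(`python analysis/01_phantom_relaxometry.py --seed 0 --out results`):
phantom relaxometry, qMT recovery, transient sensitivity, group models.
The same workflows are exposed on the command line (`nmmt run qmt_invivo
--seed 0 --out results`, plus `make-zspec`, `fit-qmt`, `mtr`, `t2star`,
`mp2rage-t1`, `drift-correct`, `simulate-transient`, `fit-transient`,
`make-cohort`, `group-stats`).

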