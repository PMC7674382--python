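# Methods

## The two-pool exchange model

All stages share one parameterization of the free-water / macromolecular
proton system (`TwoPoolParams`): longitudinal rates R1f, R1r (1/s),
transverse times T2f (tens–hundreds of ms), T2r (~10 μs), the
restricted→free exchange rate krf (Hz) and the pool size ratio
f = kfr/krf (dimensionless; printed as percent at every I/O boundary).
The reverse rate kfr is never stored — it is always derived as f·krf, so
detailed balance cannot be violated by construction.  The equilibrium
restricted magnetization defaults to M0r = f·M0f with M0f = 1.

The coupled longitudinal equations are implemented in the detailed-balance
form (kfr out of the free pool, krf out of the restricted pool).  One
widely circulated statement of these equations repeats kfr in both
exchange terms; that form is inconsistent with f = kfr/krf and with the
steady-state model below, so the standard form is used throughout.

## Lineshapes and saturation rates

Off-resonance RF saturates the restricted pool at
Wr = π·ω₁²·G(Δ, T2r) and the free pool (direct saturation) at
Wf = (ω₁/2πΔ)²/T2f, with ω₁ the continuous-wave-power-equivalent (CWPE)
amplitude in rad/s (microtesla accepted at boundaries, converted with
γ = 42.577 MHz/T).

G is the absorption lineshape (super-Lorentzian default; Gaussian and
Lorentzian available).  **Normalization convention:** G integrates to 1
over the offset in Hz.  (The common alternative normalizes over angular
frequency and is a factor 2π smaller; either convention is self-consistent
as long as generation and fitting share it, which they do here.  Absolute
Wr values in this package are therefore 2π larger than under the
angular-frequency convention at the same nominal amplitude.)

The super-Lorentzian angular integral is evaluated with a fixed 256-node
Gauss–Legendre rule graded exponentially toward the magic angle
(3cos²θ = 1), accurate to <1e-9 relative against adaptive quadrature for
Δ·T2r ∈ [2e-7, 1]; beyond Δ·T2r = 1 the lineshape is below 1e-8 of its
in-band values and is returned as 0.  The on-resonance singularity is
handled by refusing evaluation below a configurable minimum offset
(default 50 Hz; the protocol never samples below 210 Hz).

**CWPE convention.**  The CWPE of a pulse train is the constant amplitude
with the same mean square power, averaged over either the train duration
(default) or the repetition period.  The gaussian-sinc envelope is a
sinc at the pulse bandwidth under a Gaussian window truncated at 3σ.
The acquisition protocol's printed CWPE values (0.061/0.107/0.153 μT for
2.215/4.430/6.740 μT peaks) are not a constant multiple of the peaks and
produce almost no saturation under the fitted tissue parameters, so they
cannot reflect a single power-averaging convention; the synthetic
generator defaults to this package's convention (≈0.842/1.683/2.561 μT
for the same train), and all fitting accepts explicit amplitude overrides
so the printed values can be used verbatim.

## Steady-state qMT fitting

The forward model is the algebraic steady state of the coupled system
under constant Wr, Wf (verified in tests against the long-time plateau of
the ODE system to <1e-3 relative).  Four parameters are free: f, krf,
T2f, T2r.  R1r is fixed at 1/s (not identifiable from z-spectra).  R1f is
constrained by the measured T1: the slow recovery eigenvalue of the 2×2
longitudinal exchange matrix must equal 1/T1_obs, solved by bracketed
root-finding in R1f ∈ (1e-3, 20) 1/s at every optimizer iterate.  This
eigenvalue definition of the observed T1 is physically equivalent to the
usual closed-form correction and is verified by eigen-decomposition.

Optimization: trust-region least squares on MTnorm residuals (uniform
weights) from 8 fixed-seed Latin-hypercube starts placed geometrically in
the bound box f ∈ [0.1, 40]%, krf ∈ [0.1, 100] Hz, T2f ∈ [20, 400] ms,
T2r ∈ [1, 50] μs; ties among minima are broken by lowest residual, then
lowest f.  All 21 grid points (3 amplitudes × 7 offsets, 210 Hz–10 kHz)
enter the fit.  B1/B0 errors are applied as a multiplicative amplitude
scale and additive offset shift (exactly invertible bookkeeping).

Noiseless self-consistency recovers all four parameters to machine
precision for every ROI preset.  Under voxel-level Rician noise the
information content matters: at SNR 50 a *single-voxel* 21-point spectrum
bounds the relative SD of f near 25% (Cramér–Rao at the truth), so the
generator models what the experiment actually fits — ROI-mean spectra;
with ~400-voxel averaging the median |error| in f is <1%.

## Transient MT

With RF off, the fractional-saturation state s = (s_f, s_r) obeys
ds/dt = A·s with A = [[−(R1f+kfr), kfr], [krf, −(R1r+krf)]]; the free-pool
signal is the exact bi-exponential obtained by eigen-decomposition
(matches ODE integration to <1e-8).  The fixed simulation set is
R1f = R1r = 1/s, f = 10%, krf = 15 Hz, initial state s_r = 1 (restricted
pool saturated), s_f = 0.05 (partial direct saturation); its eigen-rates
are 1.0 and 17.5 1/s and the timeline peaks at 145.8 ms.  Sweeps vary one
parameter over R1f 0.25–2 1/s, R1r 1–4 1/s, krf 20–80 Hz, f 1–18% with
the rest fixed; the timeline spread is dominated by f (early delays) and
R1f (late delays), with krf and R1r contributing little — which is what
makes the transient experiment diagnostic for f.

On-resonance inversion is modelled as s_f = 2 with s_r = 1: the
broad-bandwidth restricted pool cannot be inverted by a selective pulse
and is treated as saturated (configurable).  The saturation pulses
themselves are not simulated; timelines start from a supplied state.

Bi-exponential fitting uses iterative nonlinear least squares (lmfit)
from four fixed starts; rates are reported slow-first.  The physical
rates are deliberately **not** back-solved from (a, λ): that requires
assuming both pools' initial magnetizations, which the experiment does
not measure.

## Relaxometry

* MTR = (TFL − MT)/TFL × 100%; MTnorm = 1 − MTR/100 (exact involution).
  Non-positive baseline voxels are masked and counted.
* T2\*: voxelwise mono-exponential fit; log-linear closed form, refined by
  NLS (default) which is less biased under Rician noise.  Scale-
  equivariant; two-echo case reduces to (TE₂−TE₁)/ln(S₁/S₂).
* T1: MP2RAGE index S₁S₂/(S₁²+S₂²) computed from the steady-state signal
  model (inversion, two flash blocks, recovery gaps), inverted through a
  T1–B1 dictionary (T1 grid 5 ms steps; B1 0.7–1.3 in 0.05 steps, nearest
  entry).  The 3 T protocol (TR 5000 ms, TI 750/2570 ms, flips 5°/4°) is
  the default; the flash-block TR (5.8 ms) and excitations per block
  (176) are realistic values for that readout and are config-overridable.
  The index is strictly monotone in T1 over 0.5–3.2 s for every
  dictionary B1; outside that range lookups clip and are counted.  Lookup
  error is bounded by the grid step (≤5 ms).
* Heating drift: a line is fitted to the interleaved unsaturated (TFL)
  observations vs session time; each MT observation is divided by the
  trend relative to its value at the first timestamp (ratio mode, which
  preserves MTR's ratio structure; subtraction mode available).  Works on
  ROI means or maps.

## ROI statistics

* Phantom: OLS of layer signal on concentration (continuous) + melanin
  model (categorical, agar reference), with the omnibus F and the
  concentration / sepia-vs-agar / dam-vs-agar t statistics.  A constant
  signal is a degenerate design and returns all-zero statistics rather
  than 0/0 ratios.
* Young/old: per (ROI, scan), intensity is z-scored across subjects
  (switchable) and regressed on group (old−young) plus AES;
  Benjamini–Hochberg adjustment across the four (ROI × scan) tests; 95%
  CIs.  Estimates are invariant to intensity offsets.
* AES: the exact published motion metric is an external toolbox; the
  surrogate here is the mean central-difference gradient magnitude over
  voxels exceeding 10% of the maximum gradient.  It is linear in edge
  height, zero for constant volumes, and decreases under blur — the
  properties needed of a motion covariate.

## Synthetic data

All magnitude data carry Rician noise (√((s+n₁)² + n₂²)); the generator's
empirical mean matches the analytic Rice mean (Laguerre form) to <0.5%.
Per-object streams derive from the master seed via
`SeedSequence(master, spawn_key=(counter,))`; regeneration is bit-exact.
Every generator serializes its full ground truth (`SyntheticTruth`).

* **Phantom:** cylindrical tube, layers stacked in z (sequential slabs,
  so overlap is impossible by construction): sepia 0.6/1.8/2.4/3.0 and
  dam 1.2/1.8/2.4/3.0 mg/ml (the two lost preparations omitted) with
  interleaved agar reference layers.  Ground truth
  T1 = 2000 − 200·c ms (agar-like 2000 ms down to 1400 ms at 3 mg/ml),
  T2\* = 70 − 8·c ms, and **identical MTnorm in every layer** — melanin
  concentration modulates relaxation but not MT, so the MTR map is flat
  across layers by construction.  Optional per-layer T1/T2\* jitter
  emulates preparation variability and makes regression statistics
  finite.
* **Z-spectra:** forward model at B1/B0-perturbed points on the
  3-amplitude × 7-offset grid; `n_averages` Rician draws are averaged to
  emulate an ROI-mean spectrum; T1_obs is the generative system's slow
  recovery time, exactly what relaxometry would measure.
* **Transient cohorts:** per-subject Rician noise on the magnitude
  Mz/M0 = 1 − s_f, then the elementwise median across subjects, matching
  the experimental reduction.  Default noise SD 0.004 ≈ SNR 30 at the
  0.11 peak saturation.
* **Group cohort:** 24 young / 15 old; young baselines (mean, SD):
  LC T1 1871 ± 80 ms, SN T1 1416 ± 35 ms, Pons-normalized MTw LC
  1.09 ± 0.05, SN 1.06 ± 0.08.  Default effects: LC T1 +1.2 pooled SD
  (96 ms) in the old group, all other effects null.  AES ~ N(1.0, 0.05)
  young, N(0.9, 0.08) old (older participants move more).  An optional
  AES→intensity coupling exists and defaults to inert.

## What the synthetic data does and does not show

The generators share their forward models with the fitting code, so
passing recovery tests demonstrates self-consistency, identifiability and
correct implementation — not that the models describe real tissue.  Real
data additionally contain B1/B0 estimation error, registration error,
partial-volume mixing, physiological noise, iron-related susceptibility
effects (relevant in SN), and lineshape misspecification; none are
emulated.  The group-model power figures (LC T1 rejected in ~60% of
cohorts at these sizes once the group-collinear motion confound is
adjusted for; MT-weighted false rejections at the nominal FDR level)
describe the synthetic conditions only.

## Numerical choices and degenerate inputs

Fit tolerances 1e-14 (xtol/ftol/gtol); R1f root-finding to 1e-13.
Multistart ties: lowest RSS, then lowest f.  Zero amplitude returns
MTnorm = 1 without lineshape evaluation.  Constant volumes give AES 0;
constant regressions give zero statistics; empty masks, single-group
cohorts, too-few echoes/timepoints/TFL observations all raise before any
computation.  Problem sizes throughout (16×16×36 phantom voxels, 100-seed
Monte-Carlo batches) are chosen so the full suite runs in a few minutes
on one CPU while leaving every statistical conclusion stable across
seeds.
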