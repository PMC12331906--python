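# Methods

## IR spectra from dipole dynamics

The infrared absorption lineshape of a molecule is proportional to the
Fourier transform of the dipole–dipole autocorrelation function (ACF) of
its dynamics.  Computing it from a molecular-dynamics dipole time series
captures anharmonic features — overtone and combination bands, mode
coupling, thermal red shifts — that a harmonic (Hessian-based)
calculation cannot produce.

Given dipoles μ(t) recorded at spacing dt over M steps, the pipeline in
`mdspectra.ir` is:

1. **Detrend**: subtract the time-mean dipole vector (the static dipole
   carries no vibrational information and would otherwise dominate the
   zero-frequency bin).
2. **ACF**: C(ℓ) = 1/(M−ℓ) · Σ_t (μ(t)−μ̄)·(μ(t+ℓ)−μ̄) for lags
   ℓ = 0 … L−1 with L = ⌊M/2⌋.  The per-lag (unbiased) normalization
   stabilizes the long-lag tail and makes a constant signal exactly
   zero.  Computed by FFT; unit tests pin it to the direct double loop
   at 1e−10 relative.
3. **Taper**: multiply C(ℓ) by the decaying half of a symmetric Blackman
   window w[n] = 0.42 − 0.5 cos(2πn/(N−1)) + 0.08 cos(4πn/(N−1)) of
   length N = 2L−1, so the ACF is untouched at lag 0 and driven smoothly
   to zero at the last lag.  This suppresses the spectral leakage a hard
   truncation would cause.
4. **Transform**: discrete Fourier transform of the periodic even
   extension of the tapered ACF (length N_ext = 2L−2; equivalent to a
   type-I cosine transform).  The wavenumber axis is uniform with
   spacing Δν = 1/(N_ext · dt · c), starting at 0.
5. **Quantum correction**: multiply by Q(ν) = x/(1−e^(−x)) with
   x = (hc/k_B)·ν/T (hc/k_B = 1.4387769 cm·K), the harmonic factor that
   maps a classical lineshape toward the quantum one.  Q(0) = 1 and Q is
   monotone increasing; `correction="none"` disables it.
6. **Truncate / normalize**: keep the first `max_points` axis points
   (default 12,000) and, by default, rescale the maximum intensity to 1.

At the reference sampling — 100 ps recorded every 2.5 fs, i.e.
M = 40,001 samples — this gives L = 20,000 lags, Δν = 0.3336 cm⁻¹, a
Nyquist limit of 6,671 cm⁻¹ (comfortably above the ≈3,700 cm⁻¹ ceiling
of vacuum IR fundamentals), and a stored range of ≈4,003 cm⁻¹ after
truncation.  The exact endpoint depends on the even-extension
convention; ours (N_ext = 2L−2) is fixed by the formula above.

Numerical choices worth knowing:

- Intensities are in arbitrary units (real part of the cosine
  transform, no absorption-coefficient prefactor): the dataset format
  this package targets stores unitless spectra.
- Small negative intensities are **retained**.  The Blackman taper's
  first sidelobe sits at −58 dB (≈1.3e−3 of the peak) and is partly
  negative; clipping would hide windowing bugs.  Tests bound the
  excursions at 2e−3 of the maximum.
- Peak *heights* of discrete spectra suffer sub-bin scalloping of a few
  percent; quantitative intensity comparisons should integrate over a
  band, which is what the linearity tests do.

## Synthetic dynamics

`mdspectra.synth` generates inputs with analytically known answers.

**Harmonic modes** — sums of cosines at chosen wavenumbers, amplitudes
and phases, with optional white Gaussian noise.  The spectrum must peak
within one bin of each constructed wavenumber and integrated band
intensities must scale with amplitude squared.

**Morse oscillator** — a 1-D anharmonic oscillator parameterized
spectroscopically by (ω_e, ω_e x_e, reduced mass), from which the well
depth D = ω_e²/(4 ω_e x_e) and decay length follow.  The trajectory
starts at the minimum with kinetic energy E = `energy_frac`·D and is
integrated by velocity Verlet.  The classical oscillation wavenumber is
exactly ω_e·√(1−E/D), so the spectrum red-shifts with energy precisely
as vibrational anharmonicity demands; at E/D = 0.1 the fundamental falls
within 2% of the quantum 1←0 term value ω_e − 2ω_e x_e.  A nonlinear
dipole μ(x) = c₁x + c₂x² modulates the overtone at twice the classical
frequency.  Two caveats the tests respect, because a single-energy
classical orbit is exactly periodic:

- its overtone sits at exactly twice its (red-shifted) fundamental, so
  "overtone below twice the fundamental" is asserted against the
  analytic 1←0 transition wavenumber, which the measured overtone
  undercuts strictly at E/D = 0.1;
- mechanical anharmonicity alone (linear dipole) already produces an
  overtone via the anharmonic x(t); the electrical channel (c₂ ≠ 0)
  interferes with it sign-dependently rather than creating it.

The integrator sub-steps internally so the symplectic energy oscillation
stays below 1e−5 relative regardless of the requested output cadence;
the recorded run is verified to hold energy to 1e−4.  The output cadence
itself must keep at least 50 samples per harmonic period.

**Shielding ensembles** — per-frame per-atom isotropic shieldings drawn
around known group-mean chemical shifts: one shared Gaussian
perturbation per group per frame (σ = `frame_sigma_ppm`) plus optional
independent atom jitter (default 0, so the hierarchical averaging
contract is exact).  Stored shieldings are σ_TMS(element) − shift, so
TMS referencing recovers the configured means.  What this emulates is
thermal frame-to-frame variation of a rigid grouping; what it does not
emulate is conformational symmetry breaking, exchange broadening, or
correlated atom motions — passing tests certify the averaging
arithmetic, not DFT shielding physics.

## NMR post-processing

Per-atom shieldings are referenced as δ = σ_TMS(element) − σ_atom
(defaults σ_TMS: 31.0 ppm for ¹H, 188.0 ppm for ¹³C in the synthetic
fixtures; real values come from the TMS footer of the input).

**Symmetry grouping** uses canonical atom ranks on the molecular graph
(RDKit, ties unbroken): carbons share a group iff their ranks coincide;
hydrogens share a group iff they are bonded to the same heavy atom or to
rank-equivalent heavy atoms.  This matches chemical equivalence for
methyl rotors and ring symmetry, and is deterministic.  Two documented
divergences from strict NMR equivalence: symmetry broken only by
conformation is ignored, and diastereotopic protons on one carbon are
grouped together (the "same carbon" rule).

**Two-level averaging**: group members are averaged within each frame,
then the per-frame group values are averaged across frames.  The
per-group standard deviation across frames uses the population
convention (denominator n) — the frames are treated as the full sampled
ensemble, and a single frame then cleanly yields zero.  `max_std` per
element is the maximum over that element's groups.  A pooled
(single-pass) ordering is available behind `order="pooled"` for
sensitivity checks; it coincides with the hierarchical mean (group sizes
are constant across frames) but differs in the std whenever atoms
scatter within a group.

The raw-text frame dialect (`frame <id> <n>` header, one
`index element x y z sigma` line per atom, optional
`TMS H <v> C <v>` footer) is this package's own minimal fixture format
with a matched writer and parser; real plane-wave-DFT logs are adapted
by a user-supplied converter.

## Similarity scoring

NMR peak lists are broadened with unit-mass Gaussian kernels of width
σ = tolerance (0.1 ppm for ¹H, 2.0 ppm for ¹³C, reflecting the ≈20-fold
difference in shift ranges) on a shared grid of step σ/5 (quadrature
error ≤ 0.1%), then compared by cosine similarity.  Two unit peaks Δ
apart score exp(−Δ²/(4σ²)).  The Gaussian kernel is a design choice —
differentiable and closed-form-testable; a boxcar kernel would count
hits inside the tolerance instead.

IR spectra are compared by cosine similarity inside spectroscopic
windows (defaults: 400–3950, 500–1500, 500–1000 cm⁻¹) without
re-broadening, after linear interpolation onto the coarser of the two
axes when resolutions differ.

## Chemical-space selection and split diagnostics

Morgan fingerprints (radius 2, 2048 bits — both configurable, as no
single convention is canonical) feed three tools: exact Tanimoto
similarity (all-zero vs all-zero defined as 1.0, all-zero vs nonzero as
0.0); per-query maximum similarity to a training set with the fraction
above 0.4 and 0.5; and k-means coverage selection — Euclidean k-means on
the dense 0/1 vectors with a fixed seed, picking the `per_cluster`
members nearest each nonempty centroid (ties to the lower id).  Empty
clusters are dropped rather than re-seeded: determinism is preferred
over exact cluster counts.  The default k should scale with corpus size
(the library default of 100 suits desk-scale corpora; corpus-scale runs
use thousands).

Murcko scaffolds (ring systems plus linkers, side chains stripped)
quantify structural novelty across a split: per-scaffold
total/train/test counts, the number of test scaffolds absent from the
training side, and top-m rankings by total or by test frequency.
Acyclic molecules map to the empty scaffold, counted but excluded from
the overlap summary.

## Dipole validation metrics

`dipole_mae` pools |Δcomponent| over frames and the three axes (the
alternative — averaging per-axis MAEs — differs only when frame counts
differ per axis, which cannot happen here; pooling is the documented
choice) and separately averages |Δnorm|.  `dipole_r2` is 1 − SS_res/SS_tot
with SS_tot about the reference's own mean (per-component means for the
pooled xyz score).  A zero-variance reference returns NaN as the
undefined-marker.  Because the denominator is the reference variance,
molecules with small, nearly constant dipoles score near or below zero
even at tiny absolute error — the low-dipole degradation the metric
suite reproduces on synthetic fixtures.

## Dataset schemas

IR rows carry `id`, `smiles`, `type` (atom species encoded B:0, Br:1,
C:2, Cl:3, F:4, H:5, I:6, N:7, O:8, P:9, S:10, Si:11; heavy atoms in
SMILES order with explicit hydrogens appended — the ordering is this
package's documented convention), the wavenumber axis and the spectrum.
Corpora are chunked into Parquet files of 20,000 rows
(`ir_chunk_{k:02d}.parquet`); 177,461 rows give eight full files plus a
17,461-row remainder.  Validation is report-based and never mutates
data; writers validate before touching the filesystem.  NMR records use
the nested per-frame layout of `mdspectra.nmr` with a JSON-lines
serialization.

## Problem sizes

The test suite and the acceptance script run full-resolution 40,001-step
spectra, 100-seed ACF and parameter-recovery sweeps, and one
177,461-record chunking pass; the whole suite completes in well under a
minute on one CPU.  Morse fixtures use dt = 0.2 fs (55 samples per
ω_e = 3000 cm⁻¹ period) over 8 ps, giving 4.2 cm⁻¹ bins — an order of
magnitude finer than the 2% tolerances they are checked against.

## Known limitations

- No absolute absorbance scale: spectra are comparable only after
  normalization or within cosine similarity.
- Graph-based equivalence cannot see conformation-dependent symmetry
  breaking or distinguish diastereotopic protons.
- The classical Morse fixture reproduces anharmonic peak *positions* by
  construction but not quantum transition *intensities*.
- The synthetic shielding generator draws i.i.d. Gaussian frame noise;
  real MD frames are autocorrelated in time.
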