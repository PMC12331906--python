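# mdspectra

Tools for building and validating computational molecular-spectroscopy
datasets: **anharmonic IR spectra** computed from dipole-moment time
series, **ensemble-averaged NMR chemical shifts** with symmetry-aware
grouping, tolerance-based **spectral similarity** scores, and
**chemical-space** utilities (Tanimoto/k-means training-set selection,
Murcko scaffold split diagnostics) together with the chunked Parquet
schemas such datasets are published in.

It is aimed at computational chemists who generate spectra from
molecular dynamics and at ML practitioners who consume such datasets and
need to reproduce, validate or extend the post-processing.

## The methods in brief

**IR.** The absorption lineshape is the Fourier transform of the
dipole–dipole autocorrelation function of an MD trajectory, which
natively contains overtones, combination bands and thermal
anharmonicity.  For dipoles μ(t) sampled every dt over M steps:

    C(ℓ) = 1/(M−ℓ) Σ_t (μ(t)−μ̄)·(μ(t+ℓ)−μ̄),   ℓ = 0 … ⌊M/2⌋−1

C(ℓ) is tapered by the decaying half of a Blackman window
w[n] = 0.42 − 0.5 cos(2πn/(N−1)) + 0.08 cos(4πn/(N−1)), cosine-transformed,
and multiplied by the harmonic quantum correction
Q(ν) = x/(1−e^(−x)), x = hcν/k_BT.  At the reference sampling (100 ps
every 2.5 fs → 40,001 steps) the axis spacing is 0.3336 cm⁻¹ and the
stored spectrum keeps the first 12,000 points (≈4,003 cm⁻¹).

**NMR.** Per-frame isotropic shieldings are referenced against TMS
(δ = σ_TMS − σ), symmetry-equivalent C and H atoms are grouped via
canonical ranks on the molecular graph, and shifts are averaged at two
levels — within each frame across group members, then across frames —
with per-group standard deviations quantifying conformational
variability.

**Similarity.** NMR peak lists are Gaussian-broadened at the element's
tolerance (0.1 ppm ¹H, 2.0 ppm ¹³C) and compared by cosine similarity;
two unit peaks Δ apart score exp(−Δ²/4σ²).  IR curves are compared by
windowed cosine similarity (400–3950, 500–1500, 500–1000 cm⁻¹).

See `docs/methods.md` for conventions, numerical choices and
limitations, and the module docstrings for API details.

## Worked example

```python
import numpy as np
from mdspectra import ir, synth, similarity, nmr

# IR: two vibrational modes -> spectrum peaks at the right wavenumbers
traj = synth.harmonic_dipole_series(
    [synth.HarmonicModeSpec(1000.0, 1.0), synth.HarmonicModeSpec(2900.0, 0.5)],
    dt_fs=2.5, n_samples=40_001,
)
spectrum = ir.ir_spectrum(traj, ir.SpectrumConfig())
peak = spectrum.wavenumbers_cm1[np.argmax(spectrum.intensities)]
print(f"{spectrum.intensities.size} points at {spectrum.resolution_cm1:.4f} cm^-1; "
      f"strongest band at {peak:.1f} cm^-1")

# NMR: ethanol's three proton environments, recovered from noisy frames
grouping = nmr.group_equivalent_atoms("CCO")
print("ethanol H groups:", grouping.h_groups)

spec = synth.SyntheticShieldingSpec(
    group_means_ppm={"C": [58.0, 18.3], "H": [1.2, 3.7, 2.6]},
    frame_sigma_ppm=1.0, n_frames=10, seed=0,
)
frames, ref = synth.synthetic_shielding_frames(spec, grouping)
record = nmr.assemble_nmr_record("CCO", frames, grouping, ref)
print("recovered 1H shifts:", [round(v, 2) for v in record.averaged_frames["h_nmr_peaks_ave"]])
print("max 1H std across frames:", round(record.h_nmr_max_std, 2), "ppm")

score = similarity.nmr_similarity(
    similarity.PeakList([18.3, 58.0]), similarity.PeakList([18.9, 60.1]), element="C")
print(f"13C similarity: {score:.3f}")
```

Output:

    12000 points at 0.3336 cm^-1; strongest band at 1000.1 cm^-1
    ethanol H groups: [[3, 4, 5], [6, 7], [8]]
    recovered 1H shifts: [1.24, 4.04, 2.84]
    max 1H std across frames: 1.17 ppm
    13C similarity: 0.868

The spectrum keeps 12,000 points at the 0.3336 cm⁻¹ resolution of a
100 ps / 2.5 fs trajectory and peaks within one bin of the constructed
1000 cm⁻¹ mode.  Ethanol's hydrogens fall into methyl (3), methylene (2)
and hydroxyl (1) groups; with 1 ppm frame noise over 10 frames the
recovered group shifts land within a standard error (1/√10 ≈ 0.32 ppm)
of the true values, and the ¹³C similarity of two slightly shifted peak
lists reflects the 2 ppm tolerance.

## Command-line tools

`compute-ir`, `simulate-dipoles`, `simulate-shieldings`,
`nmr-aggregate`, `compare-spectra {ir,nmr}`, `select-train`,
`scaffold-stats`, `dipole-metrics`, `validate-dataset`, `chunk-write` —
each a thin wrapper over the library; `--help` documents the flags, e.g.

    compute-ir --dipoles dipoles.txt --temperature 300 --correction harmonic \
               --max-points 12000 --normalize --out spectrum.txt

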