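"""Synthetic dipole trajectories and shielding ensembles with known structure.

These generators exist so every downstream stage — ACF, windowed Fourier
transform, quantum correction, two-level NMR averaging, dataset writers —
can be exercised against analytically known answers:

* :func:`harmonic_dipole_series` builds a sum-of-cosines dipole whose
  spectrum must peak at the constructed wavenumbers with intensities
  proportional to amplitude squared.
* :func:`morse_dipole_series` integrates a 1-D Morse oscillator, whose
  classical oscillation frequency ``omega_e * sqrt(1 - E/D)`` red-shifts
  with energy exactly as vibrational anharmonicity demands, and whose
  nonlinear dipole exposes an overtone — the feature a harmonic
  (Hessian-based) treatment cannot produce.
* :func:`synthetic_shielding_frames` draws per-frame shieldings around
  known group means so the hierarchical frame/group averaging can be
  checked as a parameter-recovery problem.
* :func:`make_synthetic_ir_records` emits schema-valid IR dataset rows
  for the chunked-Parquet writers.

All generators are deterministic under an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import AMU_KG, C_CM_PER_FS, C_CM_PER_S, HC_J_CM
from .exceptions import InvalidArgumentError
from .ir import DipoleTrajectory, nyquist_wavenumber

__all__ = [
    "HarmonicModeSpec",
    "MorseOscillatorSpec",
    "SyntheticShieldingSpec",
    "harmonic_dipole_series",
    "morse_dipole_series",
    "morse_transition_wavenumber",
    "synthetic_shielding_frames",
    "make_synthetic_ir_records",
]


@dataclass
class HarmonicModeSpec:
    """One cosine component of a synthetic dipole signal."""

    wavenumber_cm1: float
    amplitude_D: float
    phase_rad: float = 0.0

    def __post_init__(self):
        if self.wavenumber_cm1 <= 0:
            raise InvalidArgumentError("mode wavenumber must be positive")
        if self.amplitude_D <= 0:
            raise InvalidArgumentError("mode amplitude must be positive")


@dataclass
class MorseOscillatorSpec:
    """Morse oscillator in spectroscopic parameters.

    ``we_cm1`` is the harmonic wavenumber omega_e, ``wexe_cm1`` the
    anharmonicity omega_e * x_e (both cm^-1), ``mass_amu`` the reduced
    mass.  The well depth follows as ``D = we^2 / (4 wexe)`` and the decay
    length from ``a = omega * sqrt(m / 2D)``.  The trajectory starts at
    the potential minimum with kinetic energy ``energy_frac * D``.  The
    dipole is a polynomial in the displacement (Angstrom):
    ``mu = dipole_linear * x + dipole_quadratic * x^2``; the quadratic
    term switches on overtone intensity.
    """

    we_cm1: float
    wexe_cm1: float
    mass_amu: float
    energy_frac: float
    dipole_linear: float = 1.0
    dipole_quadratic: float = 0.0

    def __post_init__(self):
        if self.wexe_cm1 <= 0 or self.wexe_cm1 >= self.we_cm1 / 10:
            raise InvalidArgumentError("require 0 < wexe < we/10")
        if not 0 < self.energy_frac < 0.8:
            raise InvalidArgumentError("energy_frac must lie in (0, 0.8)")
        if self.mass_amu <= 0:
            raise InvalidArgumentError("mass must be positive")

    @property
    def well_depth_cm1(self) -> float:
        return self.we_cm1**2 / (4.0 * self.wexe_cm1)

    def classical_wavenumber_cm1(self) -> float:
        """Exact oscillation wavenumber at the configured energy."""
        return self.we_cm1 * math.sqrt(1.0 - self.energy_frac)


def morse_transition_wavenumber(we_cm1: float, wexe_cm1: float, v_upper: int) -> float:
    """Quantum term-value difference ``nu(v<-0) = we*v - wexe*v*(v+1)``."""
    return we_cm1 * v_upper - wexe_cm1 * v_upper * (v_upper + 1)


@dataclass
class SyntheticShieldingSpec:
    """Known group structure for synthetic shielding ensembles.

    ``group_means_ppm`` maps element symbol ("H" / "C") to the true
    chemical shift of each symmetry group; ``frame_sigma_ppm`` is the
    frame-to-frame standard deviation shared by all members of a group
    (scalar, applied to every group).  ``atom_jitter_ppm`` adds optional
    independent per-atom noise; it defaults to 0 so the two-level
    averaging contract is exactly checkable.
    """

    group_means_ppm: Mapping[str, Sequence[float]]
    frame_sigma_ppm: float
    n_frames: int
    seed: int = 0
    atom_jitter_ppm: float = 0.0

    def __post_init__(self):
        if self.frame_sigma_ppm < 0 or self.atom_jitter_ppm < 0:
            raise InvalidArgumentError("noise scales must be >= 0")
        if self.n_frames < 1:
            raise InvalidArgumentError("need at least one frame")


def harmonic_dipole_series(
    modes: Sequence[HarmonicModeSpec],
    dt_fs: float,
    n_samples: int,
    noise_sigma_D: float = 0.0,
    seed: int = 0,
    molecule_id: str = "synthetic-harmonic",
) -> DipoleTrajectory:
    """Sum-of-cosines dipole along x with optional white Gaussian noise."""
    if n_samples < 4:
        raise InvalidArgumentError("need at least 4 samples")
    nyq = nyquist_wavenumber(dt_fs)
    for k, mode in enumerate(modes):
        if mode.wavenumber_cm1 >= nyq:
            raise InvalidArgumentError(
                f"mode {k} at {mode.wavenumber_cm1} cm^-1 is aliased: "
                f"Nyquist limit at dt={dt_fs} fs is {nyq:.1f} cm^-1"
            )
    t = np.arange(n_samples) * dt_fs
    mu = np.zeros((n_samples, 3))
    for mode in modes:
        omega = 2.0 * np.pi * C_CM_PER_FS * mode.wavenumber_cm1  # rad/fs
        mu[:, 0] += mode.amplitude_D * np.cos(omega * t + mode.phase_rad)
    if noise_sigma_D > 0:
        rng = np.random.default_rng(seed)
        mu[:, 0] += rng.normal(0.0, noise_sigma_D, n_samples)
    return DipoleTrajectory(dt_fs=dt_fs, dipoles=mu, molecule_id=molecule_id)


def _morse_force(x: np.ndarray | float, D_J: float, a_per_m: float) -> float:
    """Force -dV/dx for V = D (1 - exp(-a x))^2."""
    e = math.exp(-a_per_m * x)
    return -2.0 * D_J * a_per_m * (1.0 - e) * e


def morse_dipole_series(
    spec: MorseOscillatorSpec,
    dt_fs: float,
    n_samples: int,
    molecule_id: str = "synthetic-morse",
) -> DipoleTrajectory:
    """Velocity-Verlet Morse dynamics sampled every ``dt_fs``.

    The output cadence must satisfy ``dt <= 1/(50 c we)`` (at least 50
    recorded points per harmonic period).  Internally the equations of
    motion are integrated with a finer sub-step chosen so the symplectic
    energy oscillation stays below 1e-5 relative, which keeps the energy
    drift of the recorded run under 1e-4 at any legal cadence.
    """
    if n_samples < 4:
        raise InvalidArgumentError("need at least 4 samples")
    period_fs = 1.0 / (C_CM_PER_FS * spec.we_cm1)
    dt_max = period_fs / 50.0
    if dt_fs > dt_max:
        raise InvalidArgumentError(
            f"dt={dt_fs} fs too coarse for we={spec.we_cm1} cm^-1; "
            f"use dt <= {dt_max:.4f} fs"
        )

    # SI setup.
    m = spec.mass_amu * AMU_KG
    D_J = spec.well_depth_cm1 * HC_J_CM
    omega = 2.0 * math.pi * C_CM_PER_S * spec.we_cm1  # rad/s
    a = omega * math.sqrt(m / (2.0 * D_J))  # 1/m
    E0 = spec.energy_frac * D_J

    # Sub-step so that (omega*dt_int)^2 / 8 <= 1e-5.
    dt_int_max_s = math.sqrt(8e-5) / omega
    n_sub = max(1, math.ceil(dt_fs * 1e-15 / dt_int_max_s))
    h = dt_fs * 1e-15 / n_sub

    x = 0.0
    v = math.sqrt(2.0 * E0 / m)
    f = _morse_force(x, D_J, a)
    xs = np.empty(n_samples)
    energies = np.empty(n_samples)
    for i in range(n_samples):
        xs[i] = x
        e = math.exp(-a * x)
        energies[i] = 0.5 * m * v * v + D_J * (1.0 - e) ** 2
        for _ in range(n_sub):
            v += 0.5 * h * f / m
            x += h * v
            f = _morse_force(x, D_J, a)
            v += 0.5 * h * f / m

    drift = float(np.max(np.abs(energies - E0)) / E0)
    if drift > 1e-4:
        raise InvalidArgumentError(
            f"integration unstable (energy drift {drift:.2e}); use a smaller dt"
        )

    x_ang = xs * 1e10
    mu = np.zeros((n_samples, 3))
    mu[:, 0] = spec.dipole_linear * x_ang + spec.dipole_quadratic * x_ang**2
    return DipoleTrajectory(dt_fs=dt_fs, dipoles=mu, molecule_id=molecule_id)


def synthetic_shielding_frames(spec: SyntheticShieldingSpec, grouping, reference=None):
    """Shielding frames whose TMS-referenced shifts recover the group means.

    Per frame, every member of a group receives the group mean plus one
    shared Gaussian frame perturbation (sigma ``frame_sigma_ppm``) plus
    optional independent atom jitter.  Stored shieldings are
    ``sigma = sigma_TMS(element) - shift`` so that TMS referencing
    reproduces the configured shift means.

    Parameters
    ----------
    grouping : AtomGrouping
        Partition of C and H atom indices (see :mod:`mdspectra.nmr`).
    reference : TMSReference, optional
        Defaults to sigma_H = 31.0 ppm, sigma_C = 188.0 ppm, typical
        DFT values for tetramethylsilane.

    Returns
    -------
    (frames, reference)
        List of :class:`~mdspectra.nmr.ShieldingFrame` and the reference used.
    """
    from .nmr import ShieldingFrame, TMSReference

    if reference is None:
        reference = TMSReference(sigma_h_ppm=31.0, sigma_c_ppm=188.0)

    groups_by_el = {"C": grouping.c_groups, "H": grouping.h_groups}
    for el, groups in groups_by_el.items():
        if groups and el not in spec.group_means_ppm:
            raise InvalidArgumentError(f"missing group means for element {el}")
        if groups and len(spec.group_means_ppm[el]) != len(groups):
            raise InvalidArgumentError(
                f"{el}: {len(groups)} groups but "
                f"{len(spec.group_means_ppm[el])} means supplied"
            )

    n_atoms = 1 + max(
        (i for groups in groups_by_el.values() for g in groups for i in g),
        default=-1,
    )
    # atoms not covered by the C/H grouping stand in for other heteroatoms
    elements = ["X"] * n_atoms
    for el, groups in groups_by_el.items():
        for g in groups:
            for i in g:
                elements[i] = el

    sigma_ref = {"H": reference.sigma_h_ppm, "C": reference.sigma_c_ppm}
    rng = np.random.default_rng(spec.seed)
    frames = []
    for f in range(spec.n_frames):
        sigma_iso = np.zeros(n_atoms)
        for el, groups in groups_by_el.items():
            for gi, g in enumerate(groups):
                shift = spec.group_means_ppm[el][gi] + rng.normal(
                    0.0, spec.frame_sigma_ppm
                )
                for i in g:
                    jitter = (
                        rng.normal(0.0, spec.atom_jitter_ppm)
                        if spec.atom_jitter_ppm > 0
                        else 0.0
                    )
                    sigma_iso[i] = sigma_ref[el] - (shift + jitter)
        frames.append(
            ShieldingFrame(
                frame_id=str(f),
                elements=list(elements),
                xyz=np.zeros((n_atoms, 3)),
                sigma_iso_ppm=sigma_iso,
            )
        )
    return frames, reference


#: small pool of parseable drug-like SMILES used for schema-valid synthetic rows
_SMILES_POOL = [
    "c1ccccc1",
    "CCO",
    "CC(=O)O",
    "c1ccncc1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "CN1CCC[C@H]1c1cccnc1",
    "C1CCOC1",
    "CC(=O)Nc1ccc(O)cc1",
    "Clc1ccccc1",
    "Brc1ccc(F)cc1",
    "CCN(CC)CC",
    "O=S(=O)(N)c1ccccc1",
    "COc1ccc(CCN)cc1",
    "CC(C)(C)OC(=O)N1CCCC1",
    "c1ccc2ccccc2c1",
    "CSc1ccccc1",
    "NC(=O)c1ccccc1",
    "OCC1OC(O)C(O)C(O)C1O",
    "CC1=CC(=O)CC(C)(C)C1",
    "Ic1ccccc1",
]


def make_synthetic_ir_records(n: int, seed: int = 0, spectrum_points: int = 8):
    """``n`` schema-valid IR dataset rows with distinct ids and short spectra.

    SMILES cycle through a fixed pool; atom-type lists follow the
    dataset convention (heavy atoms in SMILES order, then hydrogens).
    Byte-identical across runs for a fixed seed.
    """
    from .dataset_io import IRRecord, type_list_for_smiles

    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    rng = np.random.default_rng(seed)
    type_cache = {s: type_list_for_smiles(s) for s in _SMILES_POOL}
    freq = np.round(np.arange(spectrum_points) * 0.3336, 4)
    records = []
    for i in range(n):
        smiles = _SMILES_POOL[i % len(_SMILES_POOL)]
        spectrum = np.round(rng.random(spectrum_points), 6)
        records.append(
            IRRecord(
                id=f"mol_{i:07d}",
                smiles=smiles,
                type=list(type_cache[smiles]),
                frequency_cm1=freq.tolist(),
                ir_spectra=spectrum.tolist(),
            )
        )
    return records
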