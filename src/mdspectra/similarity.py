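"""Spectral similarity scoring.

NMR peak lists are compared by broadening each stick spectrum with a
Gaussian kernel whose width equals the element's chemical-shift
tolerance (0.1 ppm for 1H, 2.0 ppm for 13C — reflecting the ~20-fold
difference in shift ranges) and taking the cosine similarity of the two
broadened curves on a shared grid.  Two unit peaks separated by Delta
with common width sigma then score exp(-Delta^2 / (4 sigma^2)), which
pins down the scale of the measure.

IR spectra are already continuous curves; they are compared by cosine
similarity restricted to spectroscopically meaningful windows — by
default the full 400-3950 cm^-1 range, the 500-1500 cm^-1 mid-infrared
and the 500-1000 cm^-1 fingerprint region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import InvalidArgumentError, UndefinedSimilarityError
from .ir import IRSpectrum

__all__ = [
    "PeakList",
    "SimilarityConfig",
    "broaden_peaks",
    "cosine_similarity",
    "nmr_similarity",
    "windowed_ir_similarity",
    "load_peak_list",
]


@dataclass
class PeakList:
    """Stick spectrum: shifts in ppm with positive weights (multiplicities)."""

    shifts_ppm: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.shifts_ppm = np.atleast_1d(np.asarray(self.shifts_ppm, dtype=float))
        if self.weights is None:
            self.weights = np.ones_like(self.shifts_ppm)
        else:
            self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.shifts_ppm.shape != self.weights.shape:
            raise InvalidArgumentError("shifts and weights must have equal length")
        if self.shifts_ppm.size == 0:
            raise InvalidArgumentError("peak list must be nonempty")
        if np.any(self.weights <= 0):
            raise InvalidArgumentError("peak weights must be positive")


@dataclass
class SimilarityConfig:
    tol_h_ppm: float = 0.1
    tol_c_ppm: float = 2.0
    #: grid spacing = tolerance * factor; 0.2 keeps quadrature error <= 0.1%
    grid_step_factor: float = 0.2
    ir_windows_cm1: tuple = ((400.0, 3950.0), (500.0, 1500.0), (500.0, 1000.0))

    def __post_init__(self):
        if self.tol_h_ppm <= 0 or self.tol_c_ppm <= 0:
            raise InvalidArgumentError("tolerances must be positive")
        for lo, hi in self.ir_windows_cm1:
            if lo >= hi:
                raise InvalidArgumentError(f"bad window ({lo}, {hi})")

    def tolerance(self, element: Literal["H", "C"]) -> float:
        if element == "H":
            return self.tol_h_ppm
        if element == "C":
            return self.tol_c_ppm
        raise InvalidArgumentError(f"unknown element {element!r}")


def broaden_peaks(peaks: PeakList, tolerance_ppm: float, grid: np.ndarray) -> np.ndarray:
    """Sum of unit-mass Gaussians (sigma = tolerance) scaled by peak weight.

    The grid must cover every peak by at least 4 tolerances on each side
    so the discretized kernel keeps its mass to within 0.1%.
    """
    grid = np.asarray(grid, dtype=float)
    if tolerance_ppm <= 0:
        raise InvalidArgumentError("tolerance must be positive")
    lo, hi = grid[0], grid[-1]
    for s in peaks.shifts_ppm:
        if s - 4 * tolerance_ppm < lo or s + 4 * tolerance_ppm > hi:
            raise InvalidArgumentError(
                f"grid [{lo}, {hi}] too narrow for peak at {s} ppm "
                f"(needs +/- {4 * tolerance_ppm} ppm)"
            )
    norm = 1.0 / (tolerance_ppm * np.sqrt(2.0 * np.pi))
    out = np.zeros_like(grid)
    for s, w in zip(peaks.shifts_ppm, peaks.weights):
        out += w * norm * np.exp(-0.5 * ((grid - s) / tolerance_ppm) ** 2)
    return out


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """``a.b / (|a||b|)`` for nonnegative vectors; errors on an all-zero input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("cosine similarity of a zero vector is undefined")
    return float(np.clip(np.dot(a, b) / (na * nb), 0.0, 1.0))


def _shared_grid(shifts: np.ndarray, tolerance: float, step_factor: float) -> np.ndarray:
    lo = float(shifts.min()) - 5.0 * tolerance
    hi = float(shifts.max()) + 5.0 * tolerance
    step = tolerance * step_factor
    n = int(np.ceil((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def nmr_similarity(
    computed: PeakList,
    reference: PeakList,
    element: Literal["H", "C"],
    config: SimilarityConfig | None = None,
) -> float:
    """Tolerance-broadened cosine similarity of two NMR peak lists."""
    if config is None:
        config = SimilarityConfig()
    tol = config.tolerance(element)
    all_shifts = np.concatenate([computed.shifts_ppm, reference.shifts_ppm])
    grid = _shared_grid(all_shifts, tol, config.grid_step_factor)
    return cosine_similarity(
        broaden_peaks(computed, tol, grid), broaden_peaks(reference, tol, grid)
    )


def windowed_ir_similarity(
    a: IRSpectrum,
    b: IRSpectrum,
    config: SimilarityConfig | None = None,
) -> dict[tuple[float, float], float]:
    """Cosine similarity of two IR spectra per spectral window.

    Spectra with mismatched axes are linearly interpolated onto the
    coarser of the two axes before windowing.
    """
    if config is None:
        config = SimilarityConfig()

    # common grid: the coarser axis
    if a.resolution_cm1 >= b.resolution_cm1:
        axis = a.wavenumbers_cm1
        ia = a.intensities
        ib = np.interp(axis, b.wavenumbers_cm1, b.intensities)
    else:
        axis = b.wavenumbers_cm1
        ib = b.intensities
        ia = np.interp(axis, a.wavenumbers_cm1, a.intensities)

    scores: dict[tuple[float, float], float] = {}
    for lo, hi in config.ir_windows_cm1:
        mask = (axis >= lo) & (axis <= hi)
        if not mask.any():
            raise InvalidArgumentError(
                f"window ({lo}, {hi}) cm^-1 lies outside both spectra"
            )
        scores[(lo, hi)] = cosine_similarity(ia[mask], ib[mask])
    return scores


def load_peak_list(path) -> PeakList:
    """Read two-column ``shift_ppm weight`` text (weight optional, default 1)."""
    data = np.loadtxt(path, ndmin=2, delimiter=None)
    if data.shape[1] == 1:
        return PeakList(shifts_ppm=data[:, 0])
    return PeakList(shifts_ppm=data[:, 0], weights=data[:, 1])
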