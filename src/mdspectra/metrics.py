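"""Dipole-prediction validation metrics.

A surrogate dipole model is judged per molecule against reference
(DFT-grade) dipoles along the same trajectory: mean absolute error of
the Cartesian components (pooled over frames and the three axes) and of
the vector norm, plus R^2 scores for both.  R^2 uses the reference's
own variance in the denominator, which is exactly what makes it
collapse toward (or below) zero for molecules whose dipole is nearly
constant or vanishing even when the absolute error is tiny — a known
reading caveat of the metric that these tools make easy to reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import InvalidArgumentError, InvalidDataError

__all__ = ["DipolePairSet", "dipole_mae", "dipole_r2", "MAEResult", "R2Result"]


@dataclass
class DipolePairSet:
    """Paired predicted/reference dipole 3-vectors for one molecule."""

    predicted: np.ndarray
    reference: np.ndarray
    molecule_id: str = ""

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        for name, arr in (("predicted", self.predicted), ("reference", self.reference)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise InvalidArgumentError(f"{name} must have shape (n, 3)")
            if not np.all(np.isfinite(arr)):
                raise InvalidDataError(f"{name} contains non-finite entries")
        if self.predicted.shape != self.reference.shape:
            raise InvalidArgumentError("predicted and reference lengths differ")
        if self.predicted.shape[0] < 2:
            raise InvalidArgumentError("need at least 2 frames")


class MAEResult(NamedTuple):
    mae_xyz: float
    mae_norm: float


class R2Result(NamedTuple):
    r2_xyz: float  # NaN when the reference components have zero variance
    r2_norm: float  # NaN when the reference norm has zero variance


def dipole_mae(pairs: DipolePairSet) -> MAEResult:
    """Component MAE (pooled over frames and x/y/z) and norm MAE."""
    diff = pairs.predicted - pairs.reference
    mae_xyz = float(np.mean(np.abs(diff)))
    norms_p = np.linalg.norm(pairs.predicted, axis=1)
    norms_r = np.linalg.norm(pairs.reference, axis=1)
    return MAEResult(mae_xyz=mae_xyz, mae_norm=float(np.mean(np.abs(norms_p - norms_r))))


def dipole_r2(pairs: DipolePairSet) -> R2Result:
    """R^2 for pooled components and for the norm, about the reference mean.

    A zero-variance reference makes the score undefined; NaN is returned
    as the undefined-marker rather than raising.
    """
    ref = pairs.reference
    pred = pairs.predicted

    ss_res = float(np.sum((pred - ref) ** 2))
    ss_tot = float(np.sum((ref - ref.mean(axis=0)) ** 2))
    r2_xyz = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan

    norms_p = np.linalg.norm(pred, axis=1)
    norms_r = np.linalg.norm(ref, axis=1)
    ss_res_n = float(np.sum((norms_p - norms_r) ** 2))
    ss_tot_n = float(np.sum((norms_r - norms_r.mean()) ** 2))
    r2_norm = 1.0 - ss_res_n / ss_tot_n if ss_tot_n > 0 else math.nan

    return R2Result(r2_xyz=r2_xyz, r2_norm=r2_norm)
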