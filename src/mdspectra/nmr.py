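"""Ensemble averaging of DFT NMR chemical shifts.

Chemical shifts computed frame-by-frame along an MD trajectory are
post-processed in three steps:

1. reference the per-atom isotropic shieldings against tetramethylsilane
   (TMS): ``delta = sigma_TMS(element) - sigma_atom``;
2. group symmetry-equivalent atoms — hydrogens bonded to the same heavy
   atom or attached to graph-equivalent heavy atoms, carbons in the same
   graph-automorphism class;
3. average hierarchically: group members within each frame first, then
   the per-frame group values across frames, with the per-group standard
   deviation across frames quantifying conformational variability.

Graph equivalence is determined from canonical atom ranks on the
molecular graph (RDKit, ties unbroken), which matches chemical
equivalence for the cases that matter here (methyl rotors, ring
symmetry) and is deterministic; symmetry broken only by conformation is
deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from rdkit import Chem

from .exceptions import (
    InvalidArgumentError,
    InvalidDataError,
    ShieldingParseError,
)

__all__ = [
    "ShieldingFrame",
    "TMSReference",
    "AtomGrouping",
    "FrameResult",
    "NMRRecord",
    "parse_shielding_output",
    "write_shielding",
    "reference_to_tms",
    "group_equivalent_atoms",
    "mol_with_explicit_hs",
    "aggregate_shifts",
    "assemble_nmr_record",
]


@dataclass
class ShieldingFrame:
    """Per-atom isotropic shieldings for one MD snapshot."""

    frame_id: str
    elements: list[str]
    xyz: np.ndarray
    sigma_iso_ppm: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.sigma_iso_ppm = np.asarray(self.sigma_iso_ppm, dtype=float)
        n = len(self.elements)
        if self.xyz.shape != (n, 3) or self.sigma_iso_ppm.shape != (n,):
            raise InvalidDataError(
                "elements, xyz and sigma_iso arrays must share one atom count"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class TMSReference:
    """DFT shieldings of the TMS protons and carbons, in ppm."""

    sigma_h_ppm: float
    sigma_c_ppm: float

    def __post_init__(self):
        if not (np.isfinite(self.sigma_h_ppm) and np.isfinite(self.sigma_c_ppm)):
            raise InvalidArgumentError("TMS shieldings must be finite")


@dataclass
class AtomGrouping:
    """Partition of carbon and hydrogen atom indices into equivalence groups.

    Indices are 0-based and refer to the fixed atom order of the frames
    (heavy atoms in SMILES order, hydrogens appended).
    """

    c_groups: list[list[int]]
    h_groups: list[list[int]]

    def __post_init__(self):
        for groups, label in ((self.c_groups, "C"), (self.h_groups, "H")):
            seen: set[int] = set()
            for g in groups:
                if not g:
                    raise InvalidArgumentError(f"empty {label} group")
                if seen & set(g):
                    raise InvalidArgumentError(f"{label} groups are not disjoint")
                seen.update(g)

    def groups_for(self, element: str) -> list[list[int]]:
        if element == "C":
            return self.c_groups
        if element == "H":
            return self.h_groups
        raise InvalidArgumentError(f"no grouping for element {element!r}")


@dataclass
class FrameResult:
    """Grouped per-frame NMR results (one Table-style nested frame entry)."""

    c_nmr_grouped_peaks: list[list[float]]
    c_nmr_peaks_ave: list[float]
    c_nmr_peaks_unsorted: list[float]
    h_nmr_grouped_peaks: list[list[float]]
    h_nmr_peaks_ave: list[float]
    h_nmr_peaks_unsorted: list[float]
    nmr_cpmd_text: str
    xyz: np.ndarray


@dataclass
class NMRRecord:
    """Aggregated multi-frame NMR record (nested dataset schema)."""

    id: str
    smiles: str
    atoms: list[str]
    xyz: np.ndarray
    c_atoms_group_index: list[list[int]]
    h_atoms_group_index: list[list[int]]
    frames: dict[str, FrameResult]
    number_of_frames: int
    frame_ids: list[str]
    averaged_frames: dict[str, list[float]]
    h_nmr_std: list[float]
    c_nmr_std: list[float]
    h_nmr_max_std: float
    c_nmr_max_std: float


# ---------------------------------------------------------------------------
# fixture shielding dialect
#
# Line 1 : "frame <frame_id> <n_atoms>"
# Atoms  : "<1-based index> <element> <x> <y> <z> <sigma_iso_ppm>"
# Footer : "TMS H <sigma_h> C <sigma_c>"   (optional)
#
# This is a deliberately minimal, documented dialect emulating the shape of
# plane-wave-DFT shielding logs; real logs are adapted by a user converter.


def parse_shielding_output(text: str) -> tuple[ShieldingFrame, TMSReference | None]:
    """Parse one shielding text block; returns the frame and optional TMS footer."""
    lines = [ln for ln in text.splitlines()]
    content = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
    if not content:
        raise ShieldingParseError("empty shielding block")

    lineno, header = content[0]
    parts = header.split()
    if len(parts) != 3 or parts[0] != "frame":
        raise ShieldingParseError(f"bad header {header!r}", lineno)
    frame_id = parts[1]
    try:
        n_atoms = int(parts[2])
    except ValueError:
        raise ShieldingParseError(f"bad atom count {parts[2]!r}", lineno) from None

    elements: list[str] = []
    xyz = np.zeros((n_atoms, 3))
    sigma = np.zeros(n_atoms)
    seen: set[int] = set()
    reference = None
    n_parsed = 0
    for lineno, line in content[1:]:
        toks = line.split()
        if toks[0] == "TMS":
            if len(toks) != 5 or toks[1] != "H" or toks[3] != "C":
                raise ShieldingParseError(f"bad TMS footer {line!r}", lineno)
            try:
                reference = TMSReference(float(toks[2]), float(toks[4]))
            except ValueError:
                raise ShieldingParseError(f"bad TMS footer {line!r}", lineno) from None
            continue
        if len(toks) != 6:
            raise ShieldingParseError(
                f"expected 'index element x y z sigma', got {line!r}", lineno
            )
        try:
            idx = int(toks[0])
            coords = [float(t) for t in toks[2:5]]
            s = float(toks[5])
        except ValueError:
            raise ShieldingParseError(f"non-numeric field in {line!r}", lineno) from None
        if idx in seen:
            raise InvalidDataError(f"duplicate atom index {idx}")
        if not 1 <= idx <= n_atoms:
            raise ShieldingParseError(f"atom index {idx} out of range", lineno)
        seen.add(idx)
        elements.append(toks[1])
        xyz[idx - 1] = coords
        sigma[idx - 1] = s
        n_parsed += 1
    if n_parsed != n_atoms:
        raise InvalidDataError(
            f"header promised {n_atoms} atoms but {n_parsed} were given"
        )
    return ShieldingFrame(frame_id, elements, xyz, sigma), reference


def write_shielding(frame: ShieldingFrame, reference: TMSReference | None = None) -> str:
    """Serialize a frame to the fixture dialect (inverse of the parser)."""
    out = [f"frame {frame.frame_id} {frame.n_atoms}"]
    for i in range(frame.n_atoms):
        x, y, z = frame.xyz[i]
        out.append(
            f"{i + 1} {frame.elements[i]} {x:.6f} {y:.6f} {z:.6f} "
            f"{frame.sigma_iso_ppm[i]:.6f}"
        )
    if reference is not None:
        out.append(f"TMS H {reference.sigma_h_ppm:.6f} C {reference.sigma_c_ppm:.6f}")
    return "\n".join(out) + "\n"


def reference_to_tms(frame: ShieldingFrame, ref: TMSReference) -> np.ndarray:
    """Per-atom chemical shifts ``delta = sigma_TMS(element) - sigma_atom``.

    Atoms that are neither H nor C get NaN (no reference defined for them).
    """
    delta = np.full(frame.n_atoms, np.nan)
    for i, el in enumerate(frame.elements):
        if el == "H":
            delta[i] = ref.sigma_h_ppm - frame.sigma_iso_ppm[i]
        elif el == "C":
            delta[i] = ref.sigma_c_ppm - frame.sigma_iso_ppm[i]
    return delta


# ---------------------------------------------------------------------------
# symmetry grouping


def mol_with_explicit_hs(smiles: str) -> Chem.Mol:
    """Parse SMILES and add explicit hydrogens (appended after heavy atoms)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidArgumentError(f"unparseable SMILES: {smiles!r}")
    return Chem.AddHs(mol)


def group_equivalent_atoms(smiles: str) -> AtomGrouping:
    """Group symmetry-equivalent C and H atoms of a molecule.

    Two hydrogens share a group iff they are bonded to the same heavy
    atom or their attachment atoms fall in the same canonical-rank
    equivalence class of the molecular graph; two carbons share a group
    iff their canonical ranks coincide.  Groups are listed in ascending
    order of their lowest atom index.  Atom indices follow RDKit's
    explicit-hydrogen order: heavy atoms in SMILES order, hydrogens
    appended.
    """
    mol = mol_with_explicit_hs(smiles)
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))

    c_classes: dict[int, list[int]] = {}
    h_classes: dict[tuple, list[int]] = {}
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if atom.GetSymbol() == "C":
            c_classes.setdefault(ranks[idx], []).append(idx)
        elif atom.GetSymbol() == "H":
            heavy = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() != 1]
            # hydrogens on graph-equivalent attachment atoms merge; a free
            # hydrogen (no heavy neighbour) keys on its own rank
            key = ("parent", ranks[heavy[0].GetIdx()]) if heavy else ("self", ranks[idx])
            h_classes.setdefault(key, []).append(idx)

    def ordered(classes):
        return sorted((sorted(v) for v in classes.values()), key=lambda g: g[0])

    return AtomGrouping(c_groups=ordered(c_classes), h_groups=ordered(h_classes))


# ---------------------------------------------------------------------------
# hierarchical averaging


@dataclass
class ShiftAggregate:
    """Output of the two-level averaging for one element's groups."""

    per_frame_group_values: np.ndarray  # (n_frames, n_groups)
    group_means: np.ndarray  # (n_groups,)
    group_stds: np.ndarray  # (n_groups,) population std across frames
    max_std: float


def aggregate_shifts(
    frames: Sequence[np.ndarray],
    grouping: AtomGrouping,
    order: Literal["frames_last", "pooled"] = "frames_last",
) -> dict[str, ShiftAggregate]:
    """Two-level averaging of per-atom shift vectors.

    ``frames`` is a sequence of equal-length per-atom shift arrays (one
    per MD frame, aligned with the grouping's atom indices).  For each
    element, each group is averaged within every frame, then the
    per-frame group values are averaged across frames; the per-group
    standard deviation (population convention, denominator n) across
    frames quantifies conformational variability, and ``max_std`` is its
    maximum over the element's groups.  A single frame yields std 0.

    ``order="pooled"`` instead pools every member-atom value of every
    frame into one flat mean/std per group — a sensitivity check that
    coincides with the hierarchical result when group sizes are equal
    across frames (they always are) and differs only in the std.
    """
    if not frames:
        raise InvalidArgumentError("need at least one frame of shifts")
    arrays = [np.asarray(f, dtype=float) for f in frames]
    n_atoms = arrays[0].shape[0]
    for k, arr in enumerate(arrays):
        if arr.shape != (n_atoms,):
            raise InvalidDataError(f"frame {k} has {arr.shape} shifts, expected ({n_atoms},)")
    stacked = np.vstack(arrays)  # (n_frames, n_atoms)

    out: dict[str, ShiftAggregate] = {}
    for element in ("H", "C"):
        groups = grouping.groups_for(element)
        n_groups = len(groups)
        per_frame = np.zeros((stacked.shape[0], n_groups))
        for gi, g in enumerate(groups):
            per_frame[:, gi] = stacked[:, g].mean(axis=1)
        if order == "frames_last":
            means = per_frame.mean(axis=0) if n_groups else np.zeros(0)
            stds = per_frame.std(axis=0, ddof=0) if n_groups else np.zeros(0)
        elif order == "pooled":
            means = np.array([stacked[:, g].mean() for g in groups])
            stds = np.array([stacked[:, g].std(ddof=0) for g in groups])
        else:
            raise InvalidArgumentError(f"unknown averaging order {order!r}")
        out[element] = ShiftAggregate(
            per_frame_group_values=per_frame,
            group_means=means,
            group_stds=stds,
            max_std=float(stds.max()) if n_groups else 0.0,
        )
    return out


def assemble_nmr_record(
    smiles: str,
    frames: Sequence[ShieldingFrame],
    grouping: AtomGrouping,
    reference: TMSReference,
    relaxed_xyz: np.ndarray | None = None,
    record_id: str = "",
) -> NMRRecord:
    """Build a full nested NMR record from frames, grouping and reference."""
    if not frames:
        raise InvalidArgumentError("need at least one frame")
    n_atoms = frames[0].n_atoms
    elements = frames[0].elements
    for fr in frames:
        if fr.n_atoms != n_atoms or fr.elements != elements:
            raise InvalidDataError("frames disagree on atom count or element order")

    shift_vectors = [reference_to_tms(fr, reference) for fr in frames]
    agg = aggregate_shifts(shift_vectors, grouping)

    frame_entries: dict[str, FrameResult] = {}
    for k, fr in enumerate(frames):
        delta = shift_vectors[k]

        def grouped(groups):
            return [[float(delta[i]) for i in g] for g in groups]

        def unsorted(element):
            return [float(delta[i]) for i, el in enumerate(elements) if el == element]

        frame_entries[fr.frame_id] = FrameResult(
            c_nmr_grouped_peaks=grouped(grouping.c_groups),
            c_nmr_peaks_ave=[float(v) for v in agg["C"].per_frame_group_values[k]],
            c_nmr_peaks_unsorted=unsorted("C"),
            h_nmr_grouped_peaks=grouped(grouping.h_groups),
            h_nmr_peaks_ave=[float(v) for v in agg["H"].per_frame_group_values[k]],
            h_nmr_peaks_unsorted=unsorted("H"),
            nmr_cpmd_text=write_shielding(fr, reference),
            xyz=fr.xyz,
        )

    return NMRRecord(
        id=record_id or smiles,
        smiles=smiles,
        atoms=list(elements),
        xyz=relaxed_xyz if relaxed_xyz is not None else frames[0].xyz,
        c_atoms_group_index=[list(g) for g in grouping.c_groups],
        h_atoms_group_index=[list(g) for g in grouping.h_groups],
        frames=frame_entries,
        number_of_frames=len(frames),
        frame_ids=[fr.frame_id for fr in frames],
        averaged_frames={
            "h_nmr_peaks_ave": [float(v) for v in agg["H"].group_means],
            "c_nmr_peaks_ave": [float(v) for v in agg["C"].group_means],
        },
        h_nmr_std=[float(v) for v in agg["H"].group_stds],
        c_nmr_std=[float(v) for v in agg["C"].group_stds],
        h_nmr_max_std=agg["H"].max_std,
        c_nmr_max_std=agg["C"].max_std,
    )
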