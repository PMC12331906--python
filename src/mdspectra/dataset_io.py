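"""Dataset schemas: chunked Parquet IR rows and nested NMR records.

The IR table has one row per molecule: ``id``, ``smiles``, ``type``
(atom species encoded by the 12-element map below), the wavenumber axis
and the quantum-corrected spectrum.  Large datasets are split into
chunks of 20,000 rows (eight full files plus a remainder at the
published corpus size of 177,461 molecules).  NMR records carry the
nested per-frame structure assembled by :mod:`mdspectra.nmr`.

Validation never mutates data: every check appends a finding to a
report, and ``strict=True`` turns a non-empty report into an error.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq
from rdkit import Chem

from .exceptions import InvalidArgumentError, InvalidDataError, SchemaError
from .nmr import NMRRecord

__all__ = [
    "SPECIES_TO_TYPE",
    "TYPE_TO_SPECIES",
    "IRRecord",
    "ChunkSpec",
    "ValidationReport",
    "type_list_for_smiles",
    "validate_ir_record",
    "chunk_slices",
    "write_ir_chunks",
    "read_ir_dataset",
    "validate_nmr_record",
    "write_nmr_records_jsonl",
    "read_nmr_records_jsonl",
]

#: element -> atom-type integer used by the dataset's ``type`` column
SPECIES_TO_TYPE = {
    "B": 0, "Br": 1, "C": 2, "Cl": 3, "F": 4, "H": 5,
    "I": 6, "N": 7, "O": 8, "P": 9, "S": 10, "Si": 11,
}
TYPE_TO_SPECIES = {v: k for k, v in SPECIES_TO_TYPE.items()}

_IR_COLUMNS = ["id", "smiles", "type", "frequency_cm1", "ir_spectra"]


@dataclass
class IRRecord:
    """One IR dataset row."""

    id: str
    smiles: str
    type: list[int]
    frequency_cm1: list[float]
    ir_spectra: list[float]


@dataclass
class ChunkSpec:
    """Chunking policy for the IR table."""

    chunk_size: int = 20_000
    pattern: str = "ir_chunk_{k:02d}.parquet"

    def __post_init__(self):
        if self.chunk_size < 1:
            raise InvalidArgumentError("chunk_size must be >= 1")


@dataclass
class ValidationReport:
    findings: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.findings.append(message)

    @property
    def ok(self) -> bool:
        return not self.findings

    def raise_if_failed(self) -> None:
        if self.findings:
            raise InvalidDataError("; ".join(self.findings))


def type_list_for_smiles(smiles: str) -> list[int]:
    """Atom-type integers: heavy atoms in SMILES order, hydrogens appended."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidArgumentError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    out = []
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in SPECIES_TO_TYPE:
            raise InvalidDataError(f"element {symbol} outside the 12-species map")
        out.append(SPECIES_TO_TYPE[symbol])
    return out


def validate_ir_record(
    record: IRRecord,
    report: ValidationReport | None = None,
    _atom_count_cache: dict | None = None,
) -> ValidationReport:
    """Check one IR row against the schema invariants."""
    rep = report if report is not None else ValidationReport()
    rid = record.id
    bad_types = [t for t in record.type if t not in TYPE_TO_SPECIES]
    if bad_types:
        rep.add(f"{rid}: atom type values {sorted(set(bad_types))} outside 0..11")
    if len(record.frequency_cm1) != len(record.ir_spectra):
        rep.add(
            f"{rid}: frequency axis ({len(record.frequency_cm1)}) and spectrum "
            f"({len(record.ir_spectra)}) lengths differ"
        )
    cache = _atom_count_cache if _atom_count_cache is not None else {}
    try:
        if record.smiles not in cache:
            cache[record.smiles] = len(type_list_for_smiles(record.smiles))
        expected = cache[record.smiles]
        if len(record.type) != expected:
            rep.add(
                f"{rid}: type list has {len(record.type)} entries but SMILES "
                f"implies {expected} atoms with explicit hydrogens"
            )
    except (InvalidArgumentError, InvalidDataError) as exc:
        rep.add(f"{rid}: {exc}")
    return rep


def chunk_slices(n: int, chunk_size: int) -> list[tuple[int, int]]:
    """Half-open (start, stop) slices splitting ``n`` records into full chunks
    plus a remainder; ``ceil(n / chunk_size)`` slices in total."""
    if n < 0 or chunk_size < 1:
        raise InvalidArgumentError("need n >= 0 and chunk_size >= 1")
    return [(i, min(i + chunk_size, n)) for i in range(0, n, chunk_size)]


def _records_to_table(records: Sequence[IRRecord]) -> pa.Table:
    return pa.table(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "type": pa.array([r.type for r in records], type=pa.list_(pa.int32())),
            "frequency_cm1": pa.array(
                [r.frequency_cm1 for r in records], type=pa.list_(pa.float64())
            ),
            "ir_spectra": pa.array(
                [r.ir_spectra for r in records], type=pa.list_(pa.float64())
            ),
        }
    )


def write_ir_chunks(
    records: Sequence[IRRecord],
    spec: ChunkSpec,
    out_dir: str | Path,
    validate: bool = True,
) -> list[Path]:
    """Write records as chunked Parquet files; validation precedes any write."""
    out_dir = Path(out_dir)
    if validate:
        report = ValidationReport()
        cache: dict = {}
        for r in records:
            validate_ir_record(r, report, _atom_count_cache=cache)
        if not report.ok:
            raise InvalidDataError(
                "invalid records rejected before writing: " + "; ".join(report.findings[:5])
            )
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, (start, stop) in enumerate(chunk_slices(len(records), spec.chunk_size)):
        path = out_dir / spec.pattern.format(k=k)
        pq.write_table(_records_to_table(records[start:stop]), path)
        paths.append(path)
    return paths


def read_ir_dataset(
    paths: Sequence[str | Path] | str | Path,
    strict: bool = False,
) -> tuple[list[IRRecord], ValidationReport]:
    """Read IR Parquet files back into records plus a validation report.

    Violations are collected, never silently dropped; ``strict=True``
    raises on any finding.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    records: list[IRRecord] = []
    report = ValidationReport()
    cache: dict = {}
    for path in paths:
        table = pq.read_table(path)
        missing = [c for c in _IR_COLUMNS if c not in table.column_names]
        extra = [c for c in table.column_names if c not in _IR_COLUMNS]
        if missing or extra:
            raise SchemaError(
                f"{path}: schema mismatch (missing columns {missing}, extra {extra})"
            )
        df = table.to_pandas()
        for row in df.itertuples(index=False):
            rec = IRRecord(
                id=row.id,
                smiles=row.smiles,
                type=list(row.type),
                frequency_cm1=list(row.frequency_cm1),
                ir_spectra=list(row.ir_spectra),
            )
            validate_ir_record(rec, report, _atom_count_cache=cache)
            records.append(rec)
    if strict:
        report.raise_if_failed()
    return records, report


# ---------------------------------------------------------------------------
# NMR record validation and JSON-lines round trip

_NMR_FRAME_KEYS = [
    "c_nmr_grouped_peaks", "c_nmr_peaks_ave", "c_nmr_peaks_unsorted",
    "h_nmr_grouped_peaks", "h_nmr_peaks_ave", "h_nmr_peaks_unsorted",
    "nmr_cpmd_text", "xyz",
]


def _is_partition(groups: list[list[int]], indices: list[int]) -> bool:
    flat = [i for g in groups for i in g]
    return sorted(flat) == sorted(indices) and len(flat) == len(set(flat))


def validate_nmr_record(record: NMRRecord) -> ValidationReport:
    """Report-based consistency check of a nested NMR record."""
    rep = ValidationReport()
    rid = record.id

    if record.number_of_frames != len(record.frame_ids):
        rep.add(
            f"{rid}: number_of_frames={record.number_of_frames} but "
            f"{len(record.frame_ids)} frame_ids"
        )
    if record.number_of_frames != len(record.frames):
        rep.add(
            f"{rid}: number_of_frames={record.number_of_frames} but "
            f"{len(record.frames)} frame entries"
        )
    if set(record.frame_ids) != set(record.frames):
        rep.add(f"{rid}: frame_ids do not match frame entry keys")

    n_h = sum(1 for el in record.atoms if el == "H")
    n_c = sum(1 for el in record.atoms if el == "C")
    h_idx = [i for i, el in enumerate(record.atoms) if el == "H"]
    c_idx = [i for i, el in enumerate(record.atoms) if el == "C"]
    if not _is_partition(record.h_atoms_group_index, h_idx):
        rep.add(f"{rid}: h_atoms_group_index is not a partition of the H atoms")
    if not _is_partition(record.c_atoms_group_index, c_idx):
        rep.add(f"{rid}: c_atoms_group_index is not a partition of the C atoms")

    for fid, fr in record.frames.items():
        for key in _NMR_FRAME_KEYS:
            if not hasattr(fr, key):
                rep.add(f"{rid}: frame {fid} missing key {key}")
        if len(fr.h_nmr_peaks_unsorted) != n_h:
            rep.add(
                f"{rid}: frame {fid} has {len(fr.h_nmr_peaks_unsorted)} unsorted "
                f"H shifts for {n_h} H atoms"
            )
        if len(fr.c_nmr_peaks_unsorted) != n_c:
            rep.add(
                f"{rid}: frame {fid} has {len(fr.c_nmr_peaks_unsorted)} unsorted "
                f"C shifts for {n_c} C atoms"
            )

    for el, stds, max_std in (
        ("H", record.h_nmr_std, record.h_nmr_max_std),
        ("C", record.c_nmr_std, record.c_nmr_max_std),
    ):
        if any(s < 0 for s in stds):
            rep.add(f"{rid}: negative {el} group std")
        if stds and not math.isclose(max_std, max(stds), rel_tol=1e-9, abs_tol=1e-12):
            rep.add(
                f"{rid}: {el.lower()}_nmr_max_std={max_std} differs from "
                f"max of group stds {max(stds)}"
            )
        if not stds and max_std != 0.0:
            rep.add(f"{rid}: {el.lower()}_nmr_max_std nonzero with no groups")
    return rep


def _record_to_jsonable(record: NMRRecord) -> dict:
    d = asdict(record)
    d["xyz"] = np.asarray(record.xyz).tolist()
    for fid, fr in d["frames"].items():
        fr["xyz"] = np.asarray(record.frames[fid].xyz).tolist()
    return d


def write_nmr_records_jsonl(records: Sequence[NMRRecord], path: str | Path) -> None:
    """JSON-lines serialization of nested NMR records (fallback container)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(_record_to_jsonable(rec), sort_keys=True) + "\n")


def read_nmr_records_jsonl(path: str | Path) -> list[NMRRecord]:
    from .nmr import FrameResult

    records = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            d["frames"] = {
                fid: FrameResult(**{**fr, "xyz": np.asarray(fr["xyz"])})
                for fid, fr in d["frames"].items()
            }
            d["xyz"] = np.asarray(d["xyz"])
            records.append(NMRRecord(**d))
    return records
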