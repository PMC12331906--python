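"""Training-set selection and split diagnostics in chemical space.

A training subset is chosen to cover chemical space by k-means
clustering of Morgan fingerprints and picking at least one molecule per
cluster (the member nearest its centroid first).  Split quality is then
diagnosed two ways: the distribution of each held-out molecule's maximum
Tanimoto similarity to the training set, and the overlap of Murcko
scaffolds (ring systems plus linkers, side chains stripped) between the
two sides of the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.cluster import KMeans

from .exceptions import InvalidArgumentError

__all__ = [
    "FingerprintSet",
    "SelectionConfig",
    "ScaffoldTable",
    "morgan_fingerprints",
    "tanimoto",
    "max_similarity_to_train",
    "MaxSimilarityResult",
    "kmeans_select",
    "scaffold_table",
]

#: scaffold key for molecules without any ring
ACYCLIC_SCAFFOLD = ""


@dataclass
class FingerprintSet:
    """Fixed-length bit fingerprints for a list of molecules."""

    ids: list[str]
    bits: np.ndarray  # (n_molecules, n_bits) uint8/bool 0-1 matrix
    radius: int = 2
    n_bits: int = 2048

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise InvalidArgumentError("bits must be a 2-D matrix")
        if self.bits.shape[0] != len(self.ids):
            raise InvalidArgumentError("one bit vector per id required")
        if self.bits.shape[1] != self.n_bits:
            raise InvalidArgumentError(
                f"bit vectors have {self.bits.shape[1]} bits, expected {self.n_bits}"
            )
        if len(set(self.ids)) != len(self.ids):
            raise InvalidArgumentError("molecule ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class SelectionConfig:
    """k-means coverage-selection parameters."""

    k: int
    seed: int = 0
    per_cluster: int = 1

    def __post_init__(self):
        if self.k < 1:
            raise InvalidArgumentError("k must be >= 1")
        if self.per_cluster < 1:
            raise InvalidArgumentError("per_cluster must be >= 1")


@dataclass
class ScaffoldTable:
    """Per-scaffold molecule counts plus split-overlap summary."""

    counts: dict[str, tuple[int, int, int]]  # scaffold -> (total, train, test)
    n_test_scaffolds: int
    n_shared_scaffolds: int
    n_test_only_scaffolds: int
    excluded_smiles: list[str]

    def top(self, m: int, by: str = "total") -> list[tuple[str, tuple[int, int, int]]]:
        """Top-``m`` scaffolds ranked by total or by test-set frequency."""
        key = {"total": 0, "test": 2}.get(by)
        if key is None:
            raise InvalidArgumentError("rank by 'total' or 'test'")
        return sorted(self.counts.items(), key=lambda kv: (-kv[1][key], kv[0]))[:m]


def morgan_fingerprints(
    smiles: Sequence[str],
    ids: Sequence[str] | None = None,
    radius: int = 2,
    n_bits: int = 2048,
) -> FingerprintSet:
    """Morgan (circular) fingerprints as a dense 0/1 matrix."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    mat = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise InvalidArgumentError(f"unparseable SMILES: {smi!r}")
        fp = gen.GetFingerprint(mol)
        mat[i, list(fp.GetOnBits())] = 1
    return FingerprintSet(
        ids=list(ids) if ids is not None else [str(i) for i in range(len(smiles))],
        bits=mat,
        radius=radius,
        n_bits=n_bits,
    )


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two bit vectors.

    Edge convention: two all-zero vectors score 1.0 (identical emptiness);
    an all-zero vector against a nonzero one scores 0.0.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise InvalidArgumentError("bit vectors must have equal length")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


@dataclass
class MaxSimilarityResult:
    ids: list[str]
    max_similarity: np.ndarray
    frac_above_04: float
    frac_above_05: float


def max_similarity_to_train(query: FingerprintSet, train: FingerprintSet) -> MaxSimilarityResult:
    """Per-query maximum Tanimoto similarity to any training molecule.

    Also reports the fraction of queries above 0.4 and 0.5, the two
    summary thresholds used to judge how close held-out molecules sit to
    the training set.
    """
    if len(train) == 0:
        raise InvalidArgumentError("training set is empty")
    if query.n_bits != train.n_bits:
        raise InvalidArgumentError("fingerprint lengths differ")
    q = query.bits.astype(np.float64)
    t = train.bits.astype(np.float64)
    inter = q @ t.T
    pop_q = q.sum(axis=1)[:, None]
    pop_t = t.sum(axis=1)[None, :]
    union = pop_q + pop_t - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    best = sim.max(axis=1)
    return MaxSimilarityResult(
        ids=list(query.ids),
        max_similarity=best,
        frac_above_04=float(np.mean(best > 0.4)),
        frac_above_05=float(np.mean(best > 0.5)),
    )


def kmeans_select(fps: FingerprintSet, config: SelectionConfig) -> list[str]:
    """Coverage selection: k-means on the bit matrix, >=per_cluster picks per cluster.

    Within a cluster, members are ranked by Euclidean distance to the
    centroid (ties broken by lexicographically lower id).  Deterministic
    under the configured seed; clusters k-means leaves empty are dropped.
    """
    n = len(fps)
    if config.k > n:
        raise InvalidArgumentError(f"k={config.k} exceeds corpus size {n}")
    X = fps.bits.astype(np.float64)
    km = KMeans(n_clusters=config.k, random_state=config.seed, n_init=10)
    labels = km.fit_predict(X)

    selected: list[str] = []
    for c in range(config.k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        order = sorted(range(members.size), key=lambda j: (d[j], fps.ids[members[j]]))
        take = min(config.per_cluster, members.size)
        selected.extend(fps.ids[members[j]] for j in order[:take])
    return sorted(selected)


def murcko_scaffold(smiles: str) -> str:
    """Canonical Murcko scaffold SMILES; empty string for acyclic molecules."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidArgumentError(f"unparseable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ACYCLIC_SCAFFOLD
    return Chem.MolToSmiles(scaffold)


def scaffold_table(
    train_smiles: Sequence[str], test_smiles: Sequence[str]
) -> ScaffoldTable:
    """Murcko-scaffold counts per split and test/train overlap summary.

    Unparseable SMILES are excluded from the counts with a warning and
    reported in ``excluded_smiles``; acyclic molecules fall under the
    empty scaffold, which is counted but ignored by the overlap summary.
    """
    counts: dict[str, list[int]] = {}
    excluded: list[str] = []

    def tally(smiles_list, column):
        for smi in smiles_list:
            try:
                scaf = murcko_scaffold(smi)
            except InvalidArgumentError:
                warnings.warn(f"excluding unparseable SMILES {smi!r}", stacklevel=2)
                excluded.append(smi)
                continue
            row = counts.setdefault(scaf, [0, 0, 0])
            row[0] += 1
            row[column] += 1

    tally(train_smiles, 1)
    tally(test_smiles, 2)

    train_scafs = {s for s, (tot, tr, te) in counts.items() if tr > 0 and s != ACYCLIC_SCAFFOLD}
    test_scafs = {s for s, (tot, tr, te) in counts.items() if te > 0 and s != ACYCLIC_SCAFFOLD}
    shared = train_scafs & test_scafs
    return ScaffoldTable(
        counts={k: tuple(v) for k, v in counts.items()},
        n_test_scaffolds=len(test_scafs),
        n_shared_scaffolds=len(shared),
        n_test_only_scaffolds=len(test_scafs - shared),
        excluded_smiles=excluded,
    )
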