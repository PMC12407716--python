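"""Structural chemospace: binary fingerprints, Tanimoto (dis)similarity and
agglomerative clustering with Newick export.

The default fingerprint is an 881-bit folded Morgan (radius 2) keyset — a
fixed-length binary descriptor of atom-centred substructures; MACCS-166
structural keys are available as an alternative dialect.  Pairwise chemical
similarity is the Tanimoto coefficient |a AND b| / |a OR b| on the bit sets;
clustering operates on the dissimilarity 1 - Tanimoto (binary Jaccard
distance, a proper metric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Fingerprint",
    "DistanceMatrix",
    "fingerprint",
    "tanimoto",
    "tanimoto_distance_matrix",
    "cluster",
    "Dendrogram",
]

logger = logging.getLogger(__name__)

#: Default fingerprint length (folded Morgan keyset).
DEFAULT_NBITS = 881

_GENERATORS: dict[int, object] = {}


def _morgan(nbits: int):
    if nbits not in _GENERATORS:
        _GENERATORS[nbits] = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=nbits
        )
    return _GENERATORS[nbits]


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary structural fingerprint."""

    bits: np.ndarray  # bool vector
    structure_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=bool))

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def bit_count(self) -> int:
        return int(self.bits.sum())


def fingerprint(
    smiles: str, structure_id: str = "", kind: str = "morgan", nbits: int = DEFAULT_NBITS
) -> Fingerprint:
    """Compute a binary fingerprint for one structure.

    ``kind`` is ``"morgan"`` (folded radius-2 circular keys, length
    ``nbits``; the default dialect) or ``"maccs"`` (166 structural keys).
    Unparseable or empty structures raise ``ValueError``.
    """
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise ValueError(f"unparseable or empty structure {smiles!r}")
    if kind == "morgan":
        bv = _morgan(nbits).GetFingerprint(mol)
        arr = np.zeros(nbits, dtype=bool)
        arr[list(bv.GetOnBits())] = True
    elif kind == "maccs":
        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(bv.GetNumBits(), dtype=bool)
        arr[list(bv.GetOnBits())] = True
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    return Fingerprint(bits=arr, structure_id=structure_id or smiles)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| in [0, 1].

    Two all-zero fingerprints are defined as identical (similarity 1.0);
    this degenerate case is logged because it usually signals featureless
    structures that the fingerprint cannot distinguish.
    """
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    union = int(np.logical_or(a.bits, b.bits).sum())
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints defined as 1.0")
        return 1.0
    return float(np.logical_and(a.bits, b.bits).sum() / union)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with labels and a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < -1e-12):
            raise ValueError("negative dissimilarity")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def tanimoto_distance_matrix(fps: list[Fingerprint]) -> DistanceMatrix:
    """Pairwise 1 - Tanimoto dissimilarity over a fingerprint list."""
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - tanimoto(fps[i], fps[j])
    return DistanceMatrix(labels=[f.structure_id for f in fps], values=d)


@dataclass
class Dendrogram:
    """Clustering result: Newick string, merge table, and leaf order."""

    newick: str
    merges: pd.DataFrame  # columns: left, right, height, size
    leaf_order: list[str]
    linkage_method: str


def cluster(dm: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a dissimilarity matrix.

    ``linkage`` is ``average`` (UPGMA, the default), ``complete`` or
    ``single``.  The Newick export carries branch lengths equal to the
    difference between parent and child merge heights; sibling order is
    deterministic (the subtree containing the lexicographically smallest
    leaf label comes first), so identical inputs give identical strings.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if dm.n < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(dm.condensed(), method=linkage)

    n = dm.n
    heights = {i: 0.0 for i in range(n)}
    newick_of: dict[int, str] = {}
    minleaf: dict[int, str] = {i: dm.labels[i] for i in range(n)}

    def node_newick(idx: int, parent_h: float) -> str:
        if idx < n:
            label = dm.labels[idx].replace(" ", "_").replace(",", "_").replace(
                "(", "_").replace(")", "_").replace(":", "_").replace(";", "_")
            return f"{label}:{parent_h - 0.0:.10g}"
        return f"{newick_of[idx]}:{parent_h - heights[idx]:.10g}"

    merges = []
    for k, (a, b, h, size) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + k
        heights[node] = float(h)
        first, second = (a, b) if minleaf[a] <= minleaf[b] else (b, a)
        newick_of[node] = f"({node_newick(first, h)},{node_newick(second, h)})"
        minleaf[node] = min(minleaf[a], minleaf[b])
        merges.append({"left": first, "right": second, "height": float(h),
                       "size": int(size)})

    root = n + len(Z) - 1
    newick = newick_of[root] + ";"
    order = _leaf_order(Z, n, minleaf, dm.labels)
    return Dendrogram(
        newick=newick,
        merges=pd.DataFrame(merges, columns=["left", "right", "height", "size"]),
        leaf_order=order,
        linkage_method=linkage,
    )


def _leaf_order(Z, n: int, minleaf: dict[int, str], labels: list[str]) -> list[str]:
    """Depth-first leaf order matching the deterministic Newick layout."""
    def walk(idx: int) -> list[int]:
        if idx < n:
            return [idx]
        a, b = int(Z[idx - n][0]), int(Z[idx - n][1])
        first, second = (a, b) if minleaf[a] <= minleaf[b] else (b, a)
        return walk(first) + walk(second)

    return [labels[i] for i in walk(n + len(Z) - 1)]
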