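"""Chemical annotation: identifier harmonization, classification bookkeeping,
genus-level novelty flagging, natural-product-likeness, and the diversity /
abundance aggregation tables.

Identifier policy
-----------------
Every structure is harmonized to the (InChI, SMILES, InChIKey) trio with
RDKit; the first 14 characters of the InChIKey — the connectivity skeleton —
are the canonical matching unit throughout.  Skeleton matching is
deliberately stereochemistry-insensitive: LC-MS annotation rarely resolves
stereocenters, and reported-compound lists routinely mix stereo variants of
the same planar structure.

Novelty
-------
A metabolite is flagged *novel* (unreported) for the genus when its skeleton
is absent from a user-supplied :class:`~phytometab.feature_table_io.ReferenceCompoundSet`
of previously reported compounds.  Features whose structure cannot be parsed
get ``novel=None`` (unknown) and are excluded from unreported counts.

NP-likeness
-----------
A fragment-contribution natural-product-likeness score: every atom-centred
circular substructure (Morgan environments up to radius 2) contributes the
log10 ratio of its frequency in a natural-product corpus versus a
synthetic-compound corpus; the molecule's score is the sum over its distinct
fragments divided by its heavy-atom count, softly clamped into [-5, 5].
Positive scores indicate natural-product-like structures.  The default
model is trained at import time from two small plain-text corpora packaged
with this module; scores are screening metadata, not a filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .feature_table_io import FeatureTable, ReferenceCompoundSet

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AnnotationError",
    "AnnotationRecord",
    "NPLikenessModel",
    "harmonize",
    "assign_primary_class",
    "flag_novelty",
    "np_likeness",
    "default_np_model",
    "relative_abundance",
    "diversity_table",
    "annotate_table",
]


class AnnotationError(ValueError):
    """A structure could not be parsed or harmonized."""


@dataclass
class AnnotationRecord:
    """Chemical identity + classification + novelty for one feature."""

    feature_id: str
    inchikey: str | None = None
    skeleton: str | None = None
    smiles: str | None = None
    inchi: str | None = None
    pathway: str = "Unclassified"
    pathway_hybrid: bool = False
    superclass: str = "Unclassified"
    superclass_hybrid: bool = False
    np_class: str = "Unclassified"
    novel: bool | None = None
    np_likeness: float | None = None
    cid: int | None = None
    error: str | None = None


# ---------------------------------------------------------------------------
# identifier harmonization


def _mol_from_feature(inchi: str | None, smiles: str | None) -> Chem.Mol:
    mol = None
    if inchi and str(inchi).strip() and not (isinstance(inchi, float) and math.isnan(inchi)):
        mol = Chem.MolFromInchi(str(inchi))
    if mol is None and smiles and str(smiles).strip() and not (
        isinstance(smiles, float) and math.isnan(smiles)
    ):
        mol = Chem.MolFromSmiles(str(smiles))
    if mol is None:
        raise AnnotationError(f"unparseable structure (inchi={inchi!r}, smiles={smiles!r})")
    return mol


def harmonize(feature: pd.Series | dict) -> AnnotationRecord:
    """Populate the canonical identifier trio for one feature.

    Accepts a feature row carrying ``inchi`` and/or ``smiles``; returns a
    partial :class:`AnnotationRecord` with InChI, canonical SMILES, InChIKey
    and skeleton filled in.  Raises :class:`AnnotationError` when neither
    representation parses.
    """
    get = feature.get
    fid = get("feature_id", None)
    if not fid and hasattr(feature, "name"):
        fid = feature.name
    mol = _mol_from_feature(get("inchi", None), get("smiles", None))
    fid = str(fid or "")
    key = Chem.MolToInchiKey(mol)
    return AnnotationRecord(
        feature_id=fid,
        inchikey=key,
        skeleton=key[:14],
        smiles=Chem.MolToSmiles(mol),
        inchi=Chem.MolToInchi(mol),
    )


def assign_primary_class(
    raw_classes: list[str], priority: list[str] | None = None
) -> tuple[str, bool]:
    """Reduce a multi-label classification to (primary label, hybrid flag).

    Empty input maps to ``("Unclassified", False)``; a single label is
    itself, non-hybrid; multiple labels pick the first by the priority order
    (alphabetical by default) and set the hybrid flag.  The result is
    invariant under permutation of the input.
    """
    labels = sorted({c.strip() for c in raw_classes if c and c.strip()})
    if not labels:
        return "Unclassified", False
    if len(labels) == 1:
        return labels[0], False
    if priority:
        rank = {p: i for i, p in enumerate(priority)}
        labels.sort(key=lambda c: (rank.get(c, len(rank)), c))
    return labels[0], True


def flag_novelty(record: AnnotationRecord, ref: ReferenceCompoundSet) -> bool | None:
    """novel = skeleton not previously reported; None when skeleton unknown."""
    if not record.skeleton:
        record.novel = None
        return None
    record.novel = record.skeleton not in ref.entries
    return record.novel


# ---------------------------------------------------------------------------
# NP-likeness

_morgan_sparse = rdFingerprintGenerator.GetMorganGenerator(radius=2)


def _fragments(mol: Chem.Mol) -> dict[int, int]:
    """Morgan environment identifiers (radius <= 2) with counts."""
    return _morgan_sparse.GetSparseCountFingerprint(mol).GetNonzeroElements()


@dataclass
class NPLikenessModel:
    """Fragment-contribution table for natural-product-likeness scoring."""

    contributions: dict[int, float] = field(default_factory=dict)
    #: Laplace smoothing pseudo-count used at training time.
    alpha: float = 1.0

    @classmethod
    def train(cls, np_smiles: list[str], sm_smiles: list[str], alpha: float = 1.0
              ) -> "NPLikenessModel":
        """Fit contributions = log10 of the smoothed frequency ratio of each
        fragment in the natural-product corpus versus the synthetic corpus."""
        def counts(smis: list[str]) -> tuple[dict[int, int], int]:
            tot: dict[int, int] = {}
            n = 0
            for s in smis:
                mol = Chem.MolFromSmiles(s)
                if mol is None:
                    raise AnnotationError(f"bad training SMILES {s!r}")
                n += 1
                for bit in _fragments(mol):
                    tot[bit] = tot.get(bit, 0) + 1
            return tot, n

        np_counts, n_np = counts(np_smiles)
        sm_counts, n_sm = counts(sm_smiles)
        contrib = {}
        for bit in set(np_counts) | set(sm_counts):
            f_np = (np_counts.get(bit, 0) + alpha) / (n_np + 2 * alpha)
            f_sm = (sm_counts.get(bit, 0) + alpha) / (n_sm + 2 * alpha)
            contrib[bit] = math.log10(f_np / f_sm)
        return cls(contributions=contrib, alpha=alpha)

    def score(self, smiles: str) -> float:
        """Score one structure; positive = natural-product-like."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise AnnotationError(f"unparseable SMILES {smiles!r}")
        n_atoms = mol.GetNumHeavyAtoms()
        if n_atoms == 0:
            raise AnnotationError("structure has no heavy atoms")
        raw = sum(self.contributions.get(b, 0.0) for b in _fragments(mol))
        return _clamp(raw / n_atoms * 10.0)


def _clamp(score: float) -> float:
    """Soft logarithmic clamp of the raw score into [-5, 5]."""
    if score > 4:
        score = 4 + math.log10(score - 3)
    elif score < -4:
        score = -4 - math.log10(-score - 3)
    return float(min(5.0, max(-5.0, score)))


def _read_smiles_resource(name: str) -> list[str]:
    text = resources.files("phytometab.data").joinpath(name).read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split("\t")[0])
    return out


_DEFAULT_MODEL: NPLikenessModel | None = None


def default_np_model() -> NPLikenessModel:
    """The packaged model, trained once per process from the bundled corpora."""
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = NPLikenessModel.train(
            _read_smiles_resource("np_training_natural.txt"),
            _read_smiles_resource("np_training_synthetic.txt"),
        )
    return _DEFAULT_MODEL


def np_likeness(smiles: str, model: NPLikenessModel | None = None) -> float:
    """Natural-product-likeness of a structure; see module docstring."""
    return (model or default_np_model()).score(smiles)


# ---------------------------------------------------------------------------
# aggregation


def relative_abundance(table: FeatureTable) -> pd.Series:
    """Per-feature percent of total signal, summed over non-blank samples.

    Percentages sum to 100 across features; invariant under uniform
    rescaling of all intensities.
    """
    ids = table.nonblank_ids
    if not ids:
        raise ValueError("no non-blank samples")
    sums = table.intensities[ids].sum(axis=1)
    grand = float(sums.sum())
    if grand <= 0:
        raise ValueError("grand intensity sum is zero")
    return 100.0 * sums / grand


def diversity_table(
    records: list[AnnotationRecord],
    level: str = "pathway",
    within_pathway: str | None = None,
) -> pd.DataFrame:
    """Count metabolites (and the unreported subset) per classification label.

    ``level`` is ``"pathway"`` or ``"superclass"``; with
    ``within_pathway`` set, only records whose primary pathway matches are
    counted (the superclass-within-pathway breakdown).  Labels whose members
    include hybrid classifications get the "+ Hybrids" suffix.  Rows are
    sorted alphabetically; ``novel=None`` records never count as unreported.
    """
    if level not in ("pathway", "superclass"):
        raise ValueError(f"unknown level {level!r}")
    rows: dict[str, dict[str, int | bool]] = {}
    for rec in records:
        if within_pathway is not None and rec.pathway != within_pathway:
            continue
        label = getattr(rec, level) or "Unclassified"
        hybrid = getattr(rec, f"{level}_hybrid")
        row = rows.setdefault(label, {"total": 0, "unreported": 0, "hybrid": False})
        row["total"] += 1
        if rec.novel is True:
            row["unreported"] += 1
        row["hybrid"] = row["hybrid"] or hybrid
    out = pd.DataFrame(
        [
            {
                "label": lab + (" + Hybrids" if row["hybrid"] else ""),
                "total": row["total"],
                "unreported": row["unreported"],
            }
            for lab, row in sorted(rows.items())
        ],
        columns=["label", "total", "unreported"],
    )
    return out


def annotate_table(
    table: FeatureTable,
    ref: ReferenceCompoundSet | None = None,
    model: NPLikenessModel | None = None,
    class_priority: list[str] | None = None,
) -> list[AnnotationRecord]:
    """Harmonize, classify, novelty-flag and score every feature of a table.

    Classification labels are consumed from the table's sidecar columns
    (``pathway`` / ``superclass`` / ``np_class``, ';'-separated for
    multi-label); structures that fail to parse are retained with
    ``novel=None`` and the error recorded.
    """
    records = []
    for fid in table.feature_ids:
        row = table.features.loc[fid]
        try:
            rec = harmonize(
                {"feature_id": fid, "inchi": row.get("inchi"), "smiles": row.get("smiles")}
            )
        except AnnotationError as exc:
            rec = AnnotationRecord(feature_id=fid, error=str(exc))
        for lvl in ("pathway", "superclass"):
            raw = row.get(lvl)
            labels = (
                str(raw).split(";")
                if raw is not None and not (isinstance(raw, float) and math.isnan(raw))
                else []
            )
            label, hybrid = assign_primary_class(labels, class_priority)
            setattr(rec, lvl, label)
            setattr(rec, f"{lvl}_hybrid", hybrid)
        raw_np = row.get("np_class")
        if raw_np is not None and not (isinstance(raw_np, float) and math.isnan(raw_np)):
            rec.np_class = str(raw_np)
        if ref is not None:
            flag_novelty(rec, ref)
        if rec.smiles:
            rec.np_likeness = np_likeness(rec.smiles, model)
        records.append(rec)
    return records


def records_to_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Flatten annotation records to a DataFrame for CSV export."""
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "inchikey": r.inchikey,
                "skeleton": r.skeleton,
                "pathway": r.pathway,
                "pathway_hybrid": r.pathway_hybrid,
                "superclass": r.superclass,
                "superclass_hybrid": r.superclass_hybrid,
                "np_class": r.np_class,
                "novel": r.novel,
                "np_likeness": r.np_likeness,
                "error": r.error,
            }
            for r in records
        ]
    )
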