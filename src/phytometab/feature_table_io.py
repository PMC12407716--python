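"""Data model and I/O for mass feature tables.

The central object is the :class:`FeatureTable`: a features x samples
intensity matrix carrying per-feature annotation metadata (m/z, retention
time, candidate structure, match-quality metrics) and per-sample design
metadata (organ, processing method, replicate, blank flag).  Missing
intensities are represented as NaN until imputation; 0 is a legal
post-imputation value and is distinct from missing.

File formats are deliberately plain: a wide CSV for the feature table
(annotation columns followed by one intensity column per sample), a small
CSV for sample metadata, and a line-oriented text file for reference
compound lists (InChIKeys, optionally tagged with a source).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SampleMeta",
    "FeatureTable",
    "ReferenceCompoundSet",
    "FEATURE_COLUMNS",
    "METADATA_COLUMNS",
    "read_feature_table",
    "read_reference_set",
    "write_outputs",
]


class SchemaError(ValueError):
    """A mandatory column is missing or malformed."""


class ValidationError(ValueError):
    """Input data violates a table invariant."""


#: Annotation columns of the feature-table CSV, in canonical order.
FEATURE_COLUMNS = [
    "feature_id",
    "mz",
    "rt",
    "name",
    "inchi",
    "smiles",
    "msms_score",
    "insilico_score",
    "top_confidence",
    "msigma",
    "mass_error_ppm",
]

METADATA_COLUMNS = ["sample_id", "organ", "processing", "replicate", "is_blank"]

_ORGANS = {"root", "seed", "none"}
_PROCESSING = {"extract", "juice", "none"}

#: Acquisition m/z range of the instrument method (Da).
MZ_RANGE = (50.0, 1300.0)


@dataclass(frozen=True)
class SampleMeta:
    """Design metadata for one sample (one column of the matrix)."""

    sample_id: str
    organ: str = "none"
    processing: str = "none"
    replicate: int = 1
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.organ not in _ORGANS:
            raise ValidationError(f"unknown organ {self.organ!r} for {self.sample_id}")
        if self.processing not in _PROCESSING:
            raise ValidationError(
                f"unknown processing {self.processing!r} for {self.sample_id}"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1 for {self.sample_id}")
        if self.is_blank and (self.organ != "none" or self.processing != "none"):
            raise ValidationError(
                f"blank sample {self.sample_id} must have organ=none, processing=none"
            )
        if not self.is_blank and (self.organ == "none" or self.processing == "none"):
            raise ValidationError(
                f"non-blank sample {self.sample_id} needs both organ and processing"
            )

    @property
    def group(self) -> str:
        """Organ x processing cell label; 'blank' for blank samples."""
        return "blank" if self.is_blank else f"{self.organ}:{self.processing}"


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with annotation and design metadata.

    Attributes
    ----------
    features : pandas.DataFrame
        Indexed by ``feature_id``; columns are :data:`FEATURE_COLUMNS` minus
        the id itself.  Optional classification sidecar columns (``pathway``,
        ``superclass``, ``np_class``) may be present.
    samples : list of SampleMeta
        Column order of ``intensities`` follows this list.
    intensities : pandas.DataFrame
        Rows indexed like ``features``, one column per ``sample_id``;
        NaN marks a missing (not-detected, pre-imputation) cell.
    """

    features: pd.DataFrame
    samples: list[SampleMeta]
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValidationError(f"duplicated sample_id(s): {dupes}")
        if list(self.intensities.columns) != sample_ids:
            raise ValidationError("intensity columns do not match sample metadata order")
        if not self.features.index.equals(self.intensities.index):
            raise ValidationError("feature index mismatch between metadata and matrix")
        if self.features.index.has_duplicates:
            dupes = sorted(self.features.index[self.features.index.duplicated()])
            raise ValidationError(f"duplicated feature_id(s): {dupes}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative intensity encountered")

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def blank_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.is_blank]

    @property
    def nonblank_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if not s.is_blank]

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def groups(self, factor: str = "cell") -> dict[str, list[str]]:
        """Map group label -> sample ids for non-blank samples.

        ``factor`` is one of ``organ``, ``processing`` or ``cell``
        (organ x processing).
        """
        out: dict[str, list[str]] = {}
        for s in self.samples:
            if s.is_blank:
                continue
            if factor == "organ":
                key = s.organ
            elif factor == "processing":
                key = s.processing
            elif factor == "cell":
                key = s.group
            else:
                raise ValueError(f"unknown factor {factor!r}")
            out.setdefault(key, []).append(s.sample_id)
        return out

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            features=self.features.loc[ids].copy(),
            samples=list(self.samples),
            intensities=self.intensities.loc[ids].copy(),
        )

    def drop_blank_columns(self) -> "FeatureTable":
        keep = [s for s in self.samples if not s.is_blank]
        return FeatureTable(
            features=self.features.copy(),
            samples=keep,
            intensities=self.intensities[[s.sample_id for s in keep]].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), list(self.samples), self.intensities.copy()
        )


_KEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")
_SKELETON_RE = re.compile(r"^[A-Z]{14}$")


@dataclass
class ReferenceCompoundSet:
    """Set of InChIKey connectivity skeletons of previously reported compounds.

    Matching is stereochemistry-insensitive: the canonical unit is the first
    14 characters of the InChIKey (the connectivity block), so stereoisomers
    of a reported compound are treated as reported.
    """

    entries: set[str] = field(default_factory=set)
    source_tags: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sk in self.entries:
            if not _SKELETON_RE.match(sk):
                raise ValidationError(f"bad skeleton {sk!r}: want 14 uppercase letters")

    def add(self, key_or_skeleton: str, source: str | None = None) -> None:
        sk = key_or_skeleton.strip().upper()
        if _KEY_RE.match(sk):
            sk = sk[:14]
        if not _SKELETON_RE.match(sk):
            raise ValidationError(f"bad identifier {key_or_skeleton!r}")
        self.entries.add(sk)
        if source:
            tags = self.source_tags.setdefault(sk, [])
            if source not in tags:
                tags.append(source)

    def __contains__(self, key_or_skeleton: str) -> bool:
        return key_or_skeleton.strip().upper()[:14] in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceCompoundSet):
            return NotImplemented
        return self.entries == other.entries and self.source_tags == other.source_tags


# ---------------------------------------------------------------------------
# readers


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer, float, np.floating)):
        return bool(int(x))
    s = str(x).strip().lower()
    if s in {"true", "t", "yes", "1"}:
        return True
    if s in {"false", "f", "no", "0", "", "nan", "na"}:
        return False
    raise ValidationError(f"cannot parse boolean {x!r}")


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample-metadata CSV into a list of :class:`SampleMeta`."""
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata file missing column(s): {missing}")
    metas = []
    for _, row in df.iterrows():
        is_blank = _parse_bool(row["is_blank"])
        organ = row["organ"].strip().lower() or "none"
        processing = row["processing"].strip().lower() or "none"
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"].strip(),
                organ=organ,
                processing=processing,
                replicate=int(float(row["replicate"] or 1)),
                is_blank=is_blank,
            )
        )
    return metas


def read_feature_table(path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Read a wide feature-table CSV plus its sample-metadata CSV.

    The feature CSV holds the annotation columns (:data:`FEATURE_COLUMNS`)
    followed by one intensity column per sample; empty cells and ``NA`` in
    intensity columns become missing markers (NaN).  Intensity column order
    is taken from the metadata file.
    """
    samples = read_sample_metadata(metadata_path)
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table missing column(s): {missing}")
    sample_ids = [s.sample_id for s in samples]
    absent = [s for s in sample_ids if s not in df.columns]
    if absent:
        raise SchemaError(f"feature table missing intensity column(s): {absent}")

    df["feature_id"] = df["feature_id"].astype(str)
    feats = df[FEATURE_COLUMNS].set_index("feature_id")
    # optional classification sidecar columns travel along if present
    for extra in ("pathway", "superclass", "np_class"):
        if extra in df.columns:
            feats[extra] = df[extra].values
    feats["top_confidence"] = [
        _parse_bool(x) if not (isinstance(x, float) and np.isnan(x)) else False
        for x in feats["top_confidence"]
    ]
    inten = df.set_index(df["feature_id"])[sample_ids].astype(float)
    inten.index.name = "feature_id"
    vals = inten.to_numpy()
    if np.nanmin(vals, initial=0.0) < 0:
        bad = inten.index[np.nanmin(np.where(np.isnan(vals), 0, vals), axis=1) < 0]
        raise ValidationError(f"negative intensity in feature(s): {list(bad)[:5]}")
    mz = feats["mz"].astype(float)
    if ((mz < MZ_RANGE[0]) | (mz > MZ_RANGE[1])).any():
        bad = list(feats.index[(mz < MZ_RANGE[0]) | (mz > MZ_RANGE[1])][:5])
        raise ValidationError(f"m/z outside acquisition range {MZ_RANGE}: {bad}")
    return FeatureTable(features=feats, samples=samples, intensities=inten)


def read_reference_set(path: str | Path) -> ReferenceCompoundSet:
    """Read a reference compound list: one InChIKey or skeleton per line,
    with an optional tab-separated source tag."""
    ref = ReferenceCompoundSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            key = parts[0].strip()
            source = parts[1].strip() if len(parts) > 1 else None
            try:
                ref.add(key, source)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return ref


# ---------------------------------------------------------------------------
# writers


def write_feature_table(
    table: FeatureTable, path: str | Path, metadata_path: str | Path
) -> None:
    """Write a FeatureTable back to the wide CSV + metadata CSV pair."""
    df = table.features.reset_index()
    inten = table.intensities.reset_index(drop=True)
    out = pd.concat([df, inten], axis=1)
    out.to_csv(path, index=False)
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "organ": s.organ,
                "processing": s.processing,
                "replicate": s.replicate,
                "is_blank": s.is_blank,
            }
            for s in table.samples
        ]
    )
    meta.to_csv(metadata_path, index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(objects: Mapping[str, object], outdir: str | Path) -> dict:
    """Write a mapping of name -> result object into ``outdir``.

    DataFrames become ``<name>.csv``; dicts/lists become ``<name>.json``;
    strings ending in ``;`` are treated as Newick trees (``<name>.nwk``);
    other strings become ``<name>.txt``.  Returns (and writes) a manifest
    with sha256 checksums, for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(objects):
        obj = objects[name]
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, index=False)
        elif isinstance(obj, (dict, list)):
            p = outdir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
        elif isinstance(obj, str) and obj.rstrip().endswith(";"):
            p = outdir / f"{name}.nwk"
            if obj.count("(") != obj.count(")"):
                raise ValidationError(f"unbalanced Newick string for {name!r}")
            p.write_text(obj.rstrip() + "\n")
        elif isinstance(obj, str):
            p = outdir / f"{name}.txt"
            p.write_text(obj)
        else:
            raise TypeError(f"cannot serialize {name!r} of type {type(obj).__name__}")
        entries.append({"name": name, "file": p.name, "sha256": _sha256(p)})
    manifest = {"files": entries}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
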