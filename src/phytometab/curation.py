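"""Feature-table curation: identification filter, imputation, noise and
blank handling.

The curation pipeline turns a raw, software-exported mass feature table into
the working table used by all downstream statistics.  Stages, in order:

1. identification filter — keep features with credible structure evidence:
   a library MS/MS match score above 600, an in-silico fragmentation score
   above 800, or a top-confidence structure prediction, combined with an
   isotope-pattern fit (mSigma) below 30 and a mass accuracy within
   +/-2.5 ppm;
2. missing-value imputation — a feature absent from *all* replicates of an
   organ x processing cell is a true zero there; a feature absent from only
   *some* replicates is imputed at (its minimum observed non-blank
   intensity) - 1, i.e. just below the detection record;
3. noise removal — drop features detected only in blanks, features whose
   blank intensities exceed their sample intensities, and features whose
   maximum sample intensity sits below the noise floor (20,000 by default);
4. blank subtraction — subtract the per-feature median blank intensity from
   every experimental sample, clamping at zero, then drop blank columns.

Every removal is tallied per feature in a :class:`CurationReport`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .feature_table_io import FeatureTable

__all__ = [
    "CurationConfig",
    "CurationReport",
    "passes_identification",
    "impute_missing",
    "remove_noise",
    "subtract_blanks",
    "curate",
]

logger = logging.getLogger(__name__)

Disposition = Literal[
    "retained", "failed_id", "blank_only", "blank_dominated", "below_floor"
]


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds of the curation pipeline.

    All score thresholds are strict except the ppm window, which is
    inclusive (an error of exactly 2.5 ppm passes).

    Parameters
    ----------
    msms_min : float
        Library MS/MS match score must exceed this (default 600).
    insilico_min : float
        In-silico fragmentation score must exceed this (default 800).
    msigma_max : float
        Isotope-pattern fit must be below this (default 30; lower = better).
    ppm_window : float
        Absolute mass error tolerance in ppm (default 2.5, inclusive).
    noise_floor : float
        Features whose maximum non-blank intensity is below this are
        removed (default 20,000).
    detect_floor : float
        Per-sample detection threshold: intensity below this counts as
        not detected (default 10,000).
    blank_rule : {"max", "median"}
        Statistic used for the blank-dominance comparison.
    impute_scope : {"cell", "global"}
        Whether all-absent imputation groups are organ x processing cells
        or the whole non-blank table.
    """

    msms_min: float = 600.0
    insilico_min: float = 800.0
    msigma_max: float = 30.0
    ppm_window: float = 2.5
    noise_floor: float = 20_000.0
    detect_floor: float = 10_000.0
    blank_rule: Literal["max", "median"] = "max"
    impute_scope: Literal["cell", "global"] = "cell"

    def __post_init__(self) -> None:
        for name in ("msms_min", "insilico_min", "msigma_max", "ppm_window",
                     "noise_floor", "detect_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.detect_floor > self.noise_floor:
            raise ValueError("detect_floor must not exceed noise_floor")
        if self.blank_rule not in ("max", "median"):
            raise ValueError(f"unknown blank_rule {self.blank_rule!r}")


@dataclass
class CurationReport:
    """Audit trail of the curation pipeline; dispositions partition the input."""

    n_input: int = 0
    n_failed_id: int = 0
    n_blank_only: int = 0
    n_blank_dominated: int = 0
    n_below_floor: int = 0
    n_retained: int = 0
    dispositions: dict[str, Disposition] = field(default_factory=dict)

    def tally(self) -> None:
        counts = pd.Series(list(self.dispositions.values())).value_counts()
        self.n_failed_id = int(counts.get("failed_id", 0))
        self.n_blank_only = int(counts.get("blank_only", 0))
        self.n_blank_dominated = int(counts.get("blank_dominated", 0))
        self.n_below_floor = int(counts.get("below_floor", 0))
        self.n_retained = int(counts.get("retained", 0))
        assert self.n_retained == self.n_input - (
            self.n_failed_id + self.n_blank_only
            + self.n_blank_dominated + self.n_below_floor
        )

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_failed_id": self.n_failed_id,
            "n_blank_only": self.n_blank_only,
            "n_blank_dominated": self.n_blank_dominated,
            "n_below_floor": self.n_below_floor,
            "n_retained": self.n_retained,
        }


def _ok(x) -> bool:
    """True if a metric value is present (not None/NaN)."""
    if x is None:
        return False
    try:
        return not math.isnan(float(x))
    except (TypeError, ValueError):
        return False


def passes_identification(feature: pd.Series, cfg: CurationConfig | None = None) -> bool:
    """Evidence-OR plus quality-gate-AND identification rule.

    A feature passes iff at least one line of structural evidence holds
    (MS/MS score > msms_min, in-silico score > insilico_min, or a
    top-confidence prediction) AND both spectral-quality gates hold
    (mSigma < msigma_max, |mass error| <= ppm_window).  A missing metric
    fails its own clause but cannot satisfy another's.
    """
    cfg = cfg or CurationConfig()
    evidence = (
        (_ok(feature.get("msms_score")) and float(feature["msms_score"]) > cfg.msms_min)
        or (_ok(feature.get("insilico_score"))
            and float(feature["insilico_score"]) > cfg.insilico_min)
        or bool(feature.get("top_confidence", False))
    )
    quality = (
        _ok(feature.get("msigma"))
        and float(feature["msigma"]) < cfg.msigma_max
        and _ok(feature.get("mass_error_ppm"))
        and abs(float(feature["mass_error_ppm"])) <= cfg.ppm_window
    )
    return evidence and quality


def impute_missing(table: FeatureTable, cfg: CurationConfig | None = None) -> FeatureTable:
    """Replace missing markers by the all-absent-zero / min-minus-one rule.

    Within each replicate group (organ x processing cell by default): a
    feature missing in every replicate becomes 0 there; a feature missing in
    some replicates is imputed at the feature's minimum observed intensity
    across all non-blank samples minus 1.  Blank columns are treated as
    their own group.  A feature observed nowhere outside blanks falls back
    to 0 (no detection record to sit below).
    """
    cfg = cfg or CurationConfig()
    out = table.copy()
    inten = out.intensities
    nonblank = table.nonblank_ids

    if cfg.impute_scope == "global":
        groups = {"all": nonblank} if nonblank else {}
    else:
        groups = table.groups("cell")
        if nonblank and not groups:
            raise ValueError("no replicate groups derivable from sample metadata")
    if table.blank_ids:
        groups = dict(groups)
        groups["blank"] = table.blank_ids
    for label, ids in groups.items():
        if not ids:
            raise ValueError(f"replicate group {label!r} has zero samples")

    feature_min = (
        inten[nonblank].min(axis=1, skipna=True) if nonblank else pd.Series(dtype=float)
    )
    for ids in groups.values():
        block = inten[ids]
        miss = block.isna()
        n_miss = miss.sum(axis=1)
        all_missing = n_miss == len(ids)
        some_missing = (n_miss > 0) & ~all_missing
        for fid in inten.index[all_missing]:
            inten.loc[fid, ids] = 0.0
        for fid in inten.index[some_missing]:
            fmin = feature_min.get(fid, np.nan)
            fill = max(fmin - 1.0, 0.0) if _ok(fmin) else 0.0
            cols = [c for c in ids if miss.at[fid, c]]
            inten.loc[fid, cols] = fill
    assert not inten.isna().any().any()
    return out


def remove_noise(
    table: FeatureTable, cfg: CurationConfig | None = None,
    report: CurationReport | None = None,
) -> tuple[FeatureTable, CurationReport]:
    """Drop blank-only, blank-dominated and below-floor features, in order.

    * blank-only: detected (>= detect_floor) in at least one blank and in no
      experimental sample;
    * blank-dominated: blank statistic (max by default) >= the same statistic
      over experimental samples;
    * below floor: maximum experimental intensity < noise_floor (strict).

    Rules requiring blanks are skipped (with a log message) when the table
    contains none.
    """
    cfg = cfg or CurationConfig()
    if report is None:
        report = CurationReport(n_input=table.n_features)
        for fid in table.feature_ids:
            report.dispositions[fid] = "retained"

    blanks, nonblank = table.blank_ids, table.nonblank_ids
    inten = table.intensities
    stat = (lambda df: df.max(axis=1)) if cfg.blank_rule == "max" else (
        lambda df: df.median(axis=1))

    keep = pd.Series(True, index=inten.index)
    if blanks:
        detected_blank = (inten[blanks] >= cfg.detect_floor).any(axis=1)
        detected_sample = (inten[nonblank] >= cfg.detect_floor).any(axis=1)
        blank_only = detected_blank & ~detected_sample
        for fid in inten.index[blank_only]:
            report.dispositions[fid] = "blank_only"
        keep &= ~blank_only

        blank_stat = stat(inten.loc[keep, blanks])
        sample_stat = stat(inten.loc[keep, nonblank])
        dominated = blank_stat >= sample_stat
        # all-zero blanks carry no contamination signal
        dominated &= inten.loc[keep, blanks].max(axis=1) > 0
        for fid in dominated.index[dominated]:
            report.dispositions[fid] = "blank_dominated"
        keep.loc[dominated.index[dominated]] = False
    else:
        logger.warning("no blank samples: blank-only/blank-dominance rules skipped")

    below = inten.loc[keep, nonblank].max(axis=1) < cfg.noise_floor
    for fid in below.index[below]:
        report.dispositions[fid] = "below_floor"
    keep.loc[below.index[below]] = False

    kept = table.subset_features(list(inten.index[keep]))
    report.tally()
    return kept, report


def subtract_blanks(table: FeatureTable) -> FeatureTable:
    """Subtract each feature's median blank intensity from every sample,
    clamp at zero, and drop the blank columns."""
    blanks = table.blank_ids
    if not blanks:
        logger.warning("no blank samples: blank subtraction is a no-op")
        return table.copy()
    med = table.intensities[blanks].median(axis=1)
    out = table.drop_blank_columns()
    out.intensities = (out.intensities.sub(med, axis=0)).clip(lower=0.0)
    return out


def curate(
    table: FeatureTable, cfg: CurationConfig | None = None
) -> tuple[FeatureTable, CurationReport]:
    """Run the full curation pipeline; returns the working table + report."""
    cfg = cfg or CurationConfig()
    report = CurationReport(n_input=table.n_features)
    for fid in table.feature_ids:
        report.dispositions[fid] = "retained"

    keep_ids = [
        fid for fid in table.feature_ids
        if passes_identification(table.features.loc[fid], cfg)
    ]
    for fid in table.feature_ids:
        if fid not in set(keep_ids):
            report.dispositions[fid] = "failed_id"
    table = table.subset_features(keep_ids)

    if table.n_features:
        table = impute_missing(table, cfg)
    table, report = remove_noise(table, cfg, report)
    table = subtract_blanks(table)
    report.tally()
    return table, report
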