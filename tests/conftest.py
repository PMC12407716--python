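"""Shared fixtures: hand-built miniature tables and the committed synthetic
fixture (80 features, seed 42) with its ground-truth sidecar."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from phytometab.feature_table_io import (
    FeatureTable,
    SampleMeta,
    read_feature_table,
    read_reference_set,
)

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture"


def build_table(data: dict[str, list[float]], samples: list[SampleMeta],
                features_meta: dict[str, dict] | None = None) -> FeatureTable:
    """Construct a FeatureTable from a feature_id -> intensity-row mapping.

    Feature metadata defaults to passing identification comfortably; NaN in
    ``data`` marks missing cells.
    """
    fids = list(data)
    defaults = {
        "mz": 300.0, "rt": 5.0, "name": "x", "inchi": None, "smiles": "CCO",
        "msms_score": 700.0, "insilico_score": 850.0, "top_confidence": False,
        "msigma": 10.0, "mass_error_ppm": 0.5,
    }
    rows = []
    for fid in fids:
        row = dict(defaults)
        row.update((features_meta or {}).get(fid, {}))
        rows.append(row)
    features = pd.DataFrame(rows, index=pd.Index(fids, name="feature_id"))
    inten = pd.DataFrame(
        np.array([data[f] for f in fids], dtype=float),
        index=features.index, columns=[s.sample_id for s in samples],
    )
    return FeatureTable(features=features, samples=samples, intensities=inten)


def design_2x2(n_reps: int = 2, n_blanks: int = 2) -> list[SampleMeta]:
    samples = []
    for organ in ("root", "seed"):
        for proc in ("extract", "juice"):
            for r in range(1, n_reps + 1):
                samples.append(SampleMeta(f"{organ}_{proc}_{r}", organ, proc, r, False))
    samples += [SampleMeta(f"blank_{r}", "none", "none", r, True)
                for r in range(1, n_blanks + 1)]
    return samples


@pytest.fixture(scope="session")
def fixture_table() -> FeatureTable:
    return read_feature_table(
        FIXTURE_DIR / "feature_table.csv", FIXTURE_DIR / "sample_metadata.csv"
    )


@pytest.fixture(scope="session")
def fixture_truth() -> pd.DataFrame:
    return pd.read_csv(FIXTURE_DIR / "ground_truth.csv")


@pytest.fixture(scope="session")
def fixture_reference():
    return read_reference_set(FIXTURE_DIR / "reference_compounds.txt")
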