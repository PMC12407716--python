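"""Synthetic feature tables with the statistical structure the analysis
assumes, plus ground truth for recovery tests.

The generator emulates a 2x2 plant-metabolomics study design — two organs
(root, seed) x two processing methods (extract, juice) with replicate
injections and solvent blanks.  Feature intensities are log-normal with
multiplicative measurement noise; planted structure includes organ- and
method-enriched features (symmetric two-fold-change splits), blank-borne
contaminants (high only in blanks, or dominating the blanks), sub-noise-floor
features, and missingness.  Every feature carries a unique chemical
structure (drawn from a packaged natural-product list, then extended with
generated unique aliphatic scaffolds), a pathway/superclass classification
from a packaged vocabulary, and a novelty ground truth realised as a
reference compound set containing exactly the "previously reported"
skeletons.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .feature_table_io import (
    FeatureTable,
    ReferenceCompoundSet,
    SampleMeta,
    write_feature_table,
)

RDLogger.DisableLog("rdApp.*")

__all__ = ["SimConfig", "simulate", "regenerate_fixture"]

ROLES = (
    "null",
    "organ_enriched_root",
    "organ_enriched_seed",
    "method_enriched_extract",
    "method_enriched_juice",
    "contaminant",
    "subfloor",
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulator.

    Defaults emulate the target design: 540 features over a 2x2 cell layout
    with 3 replicates per cell and 2 blanks; log-normal baselines around
    1e5 counts, 15% multiplicative noise CV, two-fold-change (log2fc=3)
    enrichment planted in 15% (organ) and 10% (method) of features, 5%
    blank contaminants, 5% sub-floor features and 5% missing cells.
    """

    n_features: int = 540
    n_reps: int = 3
    n_blanks: int = 2
    baseline_log_mean: float = float(np.log(1e5))
    baseline_log_sd: float = 1.0
    noise_cv: float = 0.15
    frac_organ_enriched: float = 0.15
    frac_method_enriched: float = 0.10
    effect_log2fc: float = 3.0
    frac_contaminant: float = 0.05
    frac_subfloor: float = 0.05
    frac_missing: float = 0.05
    frac_known: float = 0.22
    detect_floor: float = 10_000.0
    noise_floor: float = 20_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1 or self.n_reps < 1 or self.n_blanks < 0:
            raise ValueError("counts must be positive (blanks may be zero)")
        fracs = (self.frac_organ_enriched, self.frac_method_enriched,
                 self.frac_contaminant, self.frac_subfloor)
        if any(not 0 <= f <= 1 for f in fracs + (self.frac_missing, self.frac_known)):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("planted fractions sum past 1")


def _design(cfg: SimConfig) -> list[SampleMeta]:
    samples = []
    for organ in ("root", "seed"):
        for proc in ("extract", "juice"):
            for r in range(1, cfg.n_reps + 1):
                samples.append(SampleMeta(
                    sample_id=f"{organ}_{proc}_{r}", organ=organ,
                    processing=proc, replicate=r, is_blank=False))
    for r in range(1, cfg.n_blanks + 1):
        samples.append(SampleMeta(sample_id=f"blank_{r}", replicate=r, is_blank=True))
    return samples


def _structure_pool(n: int, rng: np.random.Generator) -> list[str]:
    """n unique SMILES: packaged natural products first, then generated
    unique linear C/O/N scaffolds (distinct connectivity skeletons)."""
    text = resources.files("phytometab.data").joinpath(
        "np_training_natural.txt").read_text()
    pool = [ln.split("\t")[0] for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    seen = set()
    smiles = []
    for s in pool:
        key = Chem.MolToInchiKey(Chem.MolFromSmiles(s))[:14]
        if key not in seen:
            seen.add(key)
            smiles.append(s)
        if len(smiles) == n:
            return smiles
    attempts = 0
    while len(smiles) < n and attempts < 100 * n:
        attempts += 1
        length = int(rng.integers(6, 24))
        atoms = rng.choice(list("CCCCON"), size=length)
        cand = "".join(atoms)
        mol = Chem.MolFromSmiles(cand)
        if mol is None:
            continue
        key = Chem.MolToInchiKey(mol)[:14]
        if key in seen:
            continue
        seen.add(key)
        smiles.append(cand)
    if len(smiles) < n:
        raise RuntimeError("could not generate enough unique structures")
    return smiles


def simulate(cfg: SimConfig) -> tuple[FeatureTable, pd.DataFrame, ReferenceCompoundSet]:
    """Generate (feature table, ground truth, reference compound set).

    Fully reproducible from ``cfg.seed``.  Ground truth columns: role,
    true_log2fc, expected_disposition, pathway, superclass, smiles,
    skeleton, in_reference.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = _design(cfg)
    nonblank = [s for s in samples if not s.is_blank]
    blanks = [s for s in samples if s.is_blank]

    n = cfg.n_features
    n_org = round(cfg.frac_organ_enriched * n)
    n_met = round(cfg.frac_method_enriched * n)
    n_con = round(cfg.frac_contaminant * n)
    n_sub = round(cfg.frac_subfloor * n)
    roles = (
        ["organ_enriched_root"] * (n_org // 2)
        + ["organ_enriched_seed"] * (n_org - n_org // 2)
        + ["method_enriched_extract"] * (n_met // 2)
        + ["method_enriched_juice"] * (n_met - n_met // 2)
        + ["contaminant"] * n_con
        + ["subfloor"] * n_sub
    )
    roles += ["null"] * (n - len(roles))
    rng.shuffle(roles)

    fids = [f"F{i + 1:04d}" for i in range(n)]
    smiles = _structure_pool(n, rng)
    skeletons = [Chem.MolToInchiKey(Chem.MolFromSmiles(s))[:14] for s in smiles]

    vocab = pd.read_csv(
        resources.files("phytometab.data").joinpath("classification_vocab.tsv"),
        sep="\t",
    )
    vrows = vocab.sample(n=n, replace=True, random_state=int(rng.integers(2**31)))
    pathways = vrows["pathway"].tolist()
    superclasses = vrows["superclass"].tolist()

    in_reference = rng.random(n) < cfg.frac_known
    ref = ReferenceCompoundSet()
    for sk, known in zip(skeletons, in_reference):
        if known:
            ref.add(sk, source="simulated-genus-records")

    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))
    half = cfg.effect_log2fc / 2.0
    inten = np.zeros((n, len(samples)))
    true_lfc = np.zeros(n)
    expected_disp = []
    contaminant_kind_cycle = 0

    for i, role in enumerate(roles):
        base = float(np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd)))
        if role.startswith(("organ_", "method_")):
            # planted effects sit clear of the noise floor in both directions
            base = max(base, 2.0 ** (half + 1) * cfg.noise_floor)
        noise = np.exp(rng.normal(0.0, sigma, size=len(samples)))
        row = np.zeros(len(samples))
        if role == "contaminant":
            # alternate blank-only and blank-dominated contaminants
            blank_level = max(base, 5.0 * cfg.detect_floor)
            if contaminant_kind_cycle % 2 == 0:
                sample_level = 0.2 * cfg.detect_floor  # undetected in samples
                expected_disp.append("blank_only")
            else:
                sample_level = 0.4 * blank_level  # detected but blank-dominated
                expected_disp.append("blank_dominated")
            contaminant_kind_cycle += 1
            for j, s in enumerate(samples):
                row[j] = (blank_level if s.is_blank else sample_level) * noise[j]
            if expected_disp[-1] == "blank_dominated":
                # guarantee the dominance margin despite noise
                bcols = [j for j, s in enumerate(samples) if s.is_blank]
                scols = [j for j, s in enumerate(samples) if not s.is_blank]
                row[bcols] = np.maximum(row[bcols], 1.05 * row[scols].max())
        elif role == "subfloor":
            level = rng.uniform(0.3, 0.9) * cfg.noise_floor
            for j, s in enumerate(samples):
                row[j] = 0.0 if s.is_blank else level * noise[j]
            row = np.minimum(row, 0.98 * cfg.noise_floor)
            expected_disp.append("below_floor")
        else:
            expected_disp.append("retained")
            if role == "organ_enriched_root":
                true_lfc[i] = -cfg.effect_log2fc  # log2fc is seed - root
            elif role == "organ_enriched_seed":
                true_lfc[i] = cfg.effect_log2fc
            elif role == "method_enriched_extract":
                true_lfc[i] = -cfg.effect_log2fc  # log2fc is juice - extract
            elif role == "method_enriched_juice":
                true_lfc[i] = cfg.effect_log2fc
            for j, s in enumerate(samples):
                if s.is_blank:
                    row[j] = 0.05 * cfg.detect_floor * noise[j]
                    continue
                fold = 1.0
                if role == "organ_enriched_root":
                    fold = 2.0 ** (half if s.organ == "root" else -half)
                elif role == "organ_enriched_seed":
                    fold = 2.0 ** (half if s.organ == "seed" else -half)
                elif role == "method_enriched_extract":
                    fold = 2.0 ** (half if s.processing == "extract" else -half)
                elif role == "method_enriched_juice":
                    fold = 2.0 ** (half if s.processing == "juice" else -half)
                row[j] = base * fold * noise[j]
        inten[i] = row

    # missingness: random non-blank cells of retained-role features
    if cfg.frac_missing > 0:
        nb_idx = [j for j, s in enumerate(samples) if not s.is_blank]
        for i, role in enumerate(roles):
            if role in ("contaminant", "subfloor"):
                continue
            miss = rng.random(len(nb_idx)) < cfg.frac_missing
            for j, m in zip(nb_idx, miss):
                if m:
                    inten[i, j] = np.nan

    features = pd.DataFrame(
        {
            "mz": rng.uniform(120.0, 1250.0, size=n).round(4),
            "rt": rng.uniform(0.5, 40.0, size=n).round(3),
            "name": [f"compound_{i + 1}" for i in range(n)],
            "inchi": [None] * n,
            "smiles": smiles,
            "msms_score": rng.uniform(650.0, 990.0, size=n).round(1),
            "insilico_score": rng.uniform(500.0, 990.0, size=n).round(1),
            "top_confidence": rng.random(n) < 0.3,
            "msigma": rng.uniform(1.0, 25.0, size=n).round(2),
            "mass_error_ppm": np.clip(rng.normal(0, 1.0, size=n), -2.4, 2.4).round(3),
            "pathway": pathways,
            "superclass": superclasses,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    intensities = pd.DataFrame(
        inten, index=features.index, columns=[s.sample_id for s in samples]
    ).round(1)
    table = FeatureTable(features=features, samples=samples, intensities=intensities)

    truth = pd.DataFrame(
        {
            "feature_id": fids,
            "role": roles,
            "true_log2fc": true_lfc,
            "expected_disposition": expected_disp,
            "pathway": pathways,
            "superclass": superclasses,
            "smiles": smiles,
            "skeleton": skeletons,
            "in_reference": in_reference,
        }
    )
    return table, truth, ref


def regenerate_fixture(cfg: SimConfig, path: str | Path) -> dict[str, str]:
    """Write the simulated table + sidecars to ``path``; returns sha256 map.

    Files: ``feature_table.csv``, ``sample_metadata.csv``,
    ``ground_truth.csv``, ``reference_compounds.txt``.  Byte-identical for
    identical configs, so fixture drift is detectable by checksum.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    table, truth, ref = simulate(cfg)
    write_feature_table(table, path / "feature_table.csv", path / "sample_metadata.csv")
    truth.to_csv(path / "ground_truth.csv", index=False)
    lines = []
    for sk in sorted(ref.entries):
        tags = ",".join(ref.source_tags.get(sk, []))
        lines.append(f"{sk}\t{tags}" if tags else sk)
    (path / "reference_compounds.txt").write_text("\n".join(lines) + "\n")
    out = {}
    for f in ("feature_table.csv", "sample_metadata.csv", "ground_truth.csv",
              "reference_compounds.txt"):
        out[f] = hashlib.sha256((path / f).read_bytes()).hexdigest()
    return out
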