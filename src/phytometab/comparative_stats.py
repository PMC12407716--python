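"""Comparative statistics for curated feature tables.

From-scratch implementations of the study-design statistics:

* **PCA** on log2(x+1)-transformed, unit-scaled intensities (prcomp-style);
* **PERMANOVA** — permutational multivariate ANOVA partitioning the sum of
  squared pairwise distances by a grouping factor, with a seeded
  permutation p-value and an exhaustive-enumeration mode for small n;
  a sequential (type-I) two-factor variant mirrors the additive
  ``organ + processing`` model;
* **moderated differential abundance** — per-feature two-sample contrasts
  with empirical-Bayes variance shrinkage: the prior degrees of freedom d0
  and prior variance s0^2 are fitted by the method of moments on log s^2
  (digamma/trigamma equations), each feature's variance is shrunk to the
  posterior (d0*s0^2 + d*s^2)/(d0 + d), and p-values use Student's t with
  d0 + d degrees of freedom;
* **Benjamini-Hochberg** step-up FDR adjustment;
* **presence/absence partitioning** at the detection threshold
  (intensity >= 10,000 counts as detected), yielding per-level detected,
  exclusive and shared feature sets (the Venn decomposition).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .chemospace import DistanceMatrix
from .feature_table_io import FeatureTable

__all__ = [
    "PcaResult",
    "PermanovaResult",
    "DiffResult",
    "PresencePartition",
    "pca",
    "distance",
    "permanova",
    "permanova_two_factor",
    "moderated_diff",
    "fit_variance_prior",
    "bh_fdr",
    "presence_partition",
]

logger = logging.getLogger(__name__)

_trigamma = lambda x: polygamma(1, x)  # noqa: E731


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_pct: np.ndarray

    def __post_init__(self) -> None:
        assert abs(float(self.explained_pct.sum()) - 100.0) < 1e-6


def pca(table: FeatureTable) -> PcaResult:
    """PCA of non-blank samples on log2(x+1), feature-wise unit-scaled.

    Constant-variance features are dropped (with a warning) before scaling.
    Component signs are fixed so the largest-magnitude loading of each
    component is positive; explained percentages cover all non-trivial
    components and sum to 100.
    """
    ids = table.nonblank_ids
    if len(ids) < 2:
        raise ValueError("PCA needs at least 2 non-blank samples")
    X = np.log2(table.intensities[ids].to_numpy(dtype=float).T + 1.0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant-variance features before scaling",
                       int((~keep).sum()))
    feats = [f for f, k in zip(table.feature_ids, keep) if k]
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n = X.shape[0]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1, X.shape[1])
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = S**2 / max(n - 1, 1)
    total = var.sum()
    cols = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(U * S, index=ids, columns=cols),
        loadings=pd.DataFrame(Vt.T, index=feats, columns=cols),
        explained_pct=100.0 * var / total,
    )


# ---------------------------------------------------------------------------
# distances


def distance(
    table: FeatureTable, metric: str = "bray-curtis", log_transform: bool | None = None
) -> DistanceMatrix:
    """Pairwise sample dissimilarities over non-blank samples.

    ``bray-curtis``: sum|x-y| / sum(x+y) on raw intensities (requires
    nonnegative data, errors on an all-zero sample).  ``euclidean``: on
    log2(x+1) by default (``log_transform=False`` for raw scale).
    """
    ids = table.nonblank_ids
    X = table.intensities[ids].to_numpy(dtype=float).T
    if metric == "bray-curtis":
        if np.any(X.sum(axis=1) == 0):
            raise ValueError("all-zero sample under bray-curtis")
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                num = np.abs(X[i] - X[j]).sum()
                den = (X[i] + X[j]).sum()
                d[i, j] = d[j, i] = num / den
    elif metric == "euclidean":
        if log_transform is None or log_transform:
            X = np.log2(X + 1.0)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(X, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels=ids, values=d)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    variable: str
    r2: float
    pseudo_f: float
    p_value: float
    n_perm: int
    seed: int | None
    df: tuple[int, int] = (0, 0)
    distance_metric: str | None = None

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "r2": self.r2,
            "pseudo_f": None if math.isinf(self.pseudo_f) else self.pseudo_f,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "df": list(self.df),
            "distance": self.distance_metric,
        }


def _ss_decomposition(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group labels.

    SS_total = (1/n) * sum_{i<j} d_ij^2;
    SS_within = sum over groups g of (1/n_g) * sum_{i<j in g} d_ij^2.
    """
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return float(ss_total), float(ss_within)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, a: int, n: int) -> float:
    ss_total, ss_within = _ss_decomposition(d2, labels)
    ss_between = ss_total - ss_within
    if ss_within <= 1e-300:
        return math.inf
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: DistanceMatrix,
    groups: list[str],
    n_perm: int = 999,
    seed: int | None = 0,
    method: str = "montecarlo",
    variable: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA with a permutation p-value.

    ``method="montecarlo"`` draws ``n_perm`` seeded label permutations and
    reports p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).  ``method="exact"``
    enumerates all n! label permutations (n <= 9) and reports the exact
    rank p = #{F_perm >= F_obs} / n! (the identity permutation counts
    itself, so p >= 1/n!).
    """
    labels = np.asarray(groups)
    n = dm.n
    if len(labels) != n:
        raise ValueError("group labels do not match matrix size")
    uniq = np.unique(labels)
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = dm.values**2
    ss_total, ss_within = _ss_decomposition(d2, labels)
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    f_obs = _pseudo_f(d2, labels, a, n)

    if method == "exact":
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9 samples")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            fp = _pseudo_f(d2, labels[list(perm)], a, n)
            count += fp >= f_obs or math.isclose(fp, f_obs, rel_tol=1e-12)
            total += 1
        p = count / total
        n_used = total
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            fp = _pseudo_f(d2, labels[rng.permutation(n)], a, n)
            count += fp >= f_obs or math.isclose(fp, f_obs, rel_tol=1e-12)
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
    return PermanovaResult(
        variable=variable, r2=float(r2), pseudo_f=float(f_obs),
        p_value=float(p), n_perm=n_used, seed=seed, df=(a - 1, n - a),
    )


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ d2 @ J


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def permanova_two_factor(
    dm: DistanceMatrix,
    factor_a: list[str],
    factor_b: list[str],
    n_perm: int = 999,
    seed: int | None = 0,
    names: tuple[str, str] = ("A", "B"),
) -> dict:
    """Sequential (type-I) two-factor PERMANOVA on Gower-centred distances.

    Fits the additive model term by term in the given order: each term's
    sum of squares is the increment in trace(H G) when its dummy columns
    join the design; pseudo-F uses the residual mean square.  P-values come
    from free permutation of sample order.  Returns per-term results plus
    the model-total R^2.
    """
    n = dm.n
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if len(a) != n or len(b) != n:
        raise ValueError("factor labels do not match matrix size")
    G = _gower_center(dm.values**2)

    def dummies(lab: np.ndarray) -> np.ndarray:
        levels = np.unique(lab)[1:]  # drop first level: intercept absorbs it
        return np.column_stack([(lab == lv).astype(float) for lv in levels]) \
            if len(levels) else np.empty((n, 0))

    ones = np.ones((n, 1))
    Xa, Xb = dummies(a), dummies(b)
    df_a, df_b = Xa.shape[1], Xb.shape[1]
    df_resid = n - 1 - df_a - df_b
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    def term_ss(Gm: np.ndarray) -> tuple[float, float, float, float]:
        h0 = _hat(ones)
        h1 = _hat(np.hstack([ones, Xa]))
        h2 = _hat(np.hstack([ones, Xa, Xb]))
        ss_a = float(np.trace((h1 - h0) @ Gm))
        ss_b = float(np.trace((h2 - h1) @ Gm))
        ss_r = float(np.trace((np.eye(n) - h2) @ Gm))
        ss_t = float(np.trace((np.eye(n) - h0) @ Gm))
        return ss_a, ss_b, ss_r, ss_t

    ss_a, ss_b, ss_r, ss_t = term_ss(G)
    ms_r = ss_r / df_resid
    f_a = (ss_a / df_a) / ms_r if ms_r > 0 else math.inf
    f_b = (ss_b / df_b) / ms_r if ms_r > 0 else math.inf

    rng = np.random.default_rng(seed)
    count_a = count_b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        pa, pb, pr, _ = term_ss(Gp)
        pms = pr / df_resid
        count_a += ((pa / df_a) / pms if pms > 0 else math.inf) >= f_a
        count_b += ((pb / df_b) / pms if pms > 0 else math.inf) >= f_b
    terms = [
        PermanovaResult(names[0], ss_a / ss_t, f_a, (count_a + 1) / (n_perm + 1),
                        n_perm, seed, (df_a, df_resid)),
        PermanovaResult(names[1], ss_b / ss_t, f_b, (count_b + 1) / (n_perm + 1),
                        n_perm, seed, (df_b, df_resid)),
    ]
    return {
        "terms": terms,
        "model_r2": (ss_a + ss_b) / ss_t,
        "residual_ss": ss_r,
        "total_ss": ss_t,
    }


# ---------------------------------------------------------------------------
# moderated differential abundance


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi-square variance prior.

    Given per-feature sample variances ``s2`` each with ``df`` degrees of
    freedom, assume s2_g | sigma2_g ~ sigma2_g * chi2_df / df with
    sigma2_g ~ s0^2 * d0 / chi2_d0, and solve the digamma/trigamma moment
    equations on z = log(s2):

        E[e] = log(s0^2) + digamma(d0/2) - log(d0/2),
        Var[e] = trigamma(df/2) + trigamma(d0/2),

    where e = z - digamma(df/2) + log(df/2) removes the sampling bias of
    the log chi-square.

    Returns ``(d0, s0_sq)``; d0 = inf (complete shrinkage) when the observed
    spread of log-variances does not exceed the chi-square sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        return math.inf, 0.0
    if pos.size < s2.size:
        logger.warning("dropping %d zero variances from prior fit",
                       s2.size - pos.size)
    z = np.log(pos)
    e = z - float(digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(e.mean())
    g = pos.size
    if g < 2:
        return math.inf, float(math.exp(emean))
    evar = float(((e - emean) ** 2).sum() / (g - 1))
    rhs = evar - float(_trigamma(df / 2.0))
    if rhs <= 0:
        return math.inf, float(math.exp(emean))
    d0 = 2.0 * trigamma_inverse(rhs)
    s0_sq = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return float(d0), float(s0_sq)


@dataclass
class DiffResult:
    """Per-feature moderated differential abundance plus prior hyperparameters."""

    table: pd.DataFrame  # feature_id, log2fc, mod_t, df_total, p, fdr, enriched_in
    d0: float
    s0_sq: float
    contrast: tuple[str, str]
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05

    @property
    def enriched(self) -> pd.DataFrame:
        return self.table[self.table["enriched_in"] != "none"]


def _infer_factor(contrast: tuple[str, str]) -> str:
    organs, procs = {"root", "seed"}, {"extract", "juice"}
    s = set(contrast)
    if s <= organs:
        return "organ"
    if s <= procs:
        return "processing"
    raise ValueError(f"cannot infer factor for contrast {contrast}")


def moderated_diff(
    table: FeatureTable,
    contrast: tuple[str, str],
    factor: str | None = None,
    d0_override: float | None = None,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> DiffResult:
    """Empirical-Bayes moderated two-group differential abundance.

    Intensities are log2(x+1)-transformed; ``log2fc`` is
    mean(group2) - mean(group1) on that scale (positive = higher in
    group2).  The variance prior (d0, s0^2) is fitted across features by
    :func:`fit_variance_prior` unless ``d0_override`` forces a limit case
    (0 = ordinary pooled t, inf = complete shrinkage).  A feature is called
    enriched when |log2fc| > ``lfc_threshold`` and BH FDR <
    ``fdr_threshold``.
    """
    factor = factor or _infer_factor(contrast)
    groups = table.groups(factor)
    g1, g2 = contrast
    for g in contrast:
        if g not in groups:
            raise ValueError(f"group {g!r} absent from factor {factor!r}")
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    X1 = np.log2(table.intensities[groups[g1]].to_numpy(dtype=float) + 1.0)
    X2 = np.log2(table.intensities[groups[g2]].to_numpy(dtype=float) + 1.0)
    n1, n2 = X1.shape[1], X2.shape[1]
    df = n1 + n2 - 2

    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    log2fc = m2 - m1
    ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_variance_prior(s2, df)
        if d0 == 0.0:
            s0_sq = float("nan")
    else:
        d0, s0_sq = fit_variance_prior(s2, df)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    elif d0 == 0.0:
        s2_post = s2
        df_total = float(df)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    t = np.where(np.isnan(t) & (log2fc == 0), 0.0, t)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    fdr = bh_fdr(p)

    call = np.full(len(p), "none", dtype=object)
    call[(log2fc > lfc_threshold) & (fdr < fdr_threshold)] = "group2"
    call[(log2fc < -lfc_threshold) & (fdr < fdr_threshold)] = "group1"
    out = pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "log2fc": log2fc,
            "s2": s2,
            "s2_post": s2_post,
            "mod_t": t,
            "df_total": df_total,
            "p": p,
            "fdr": fdr,
            "enriched_in": [g2 if c == "group2" else g1 if c == "group1" else "none"
                            for c in call],
        }
    )
    return DiffResult(table=out, d0=d0, s0_sq=s0_sq, contrast=contrast,
                      lfc_threshold=lfc_threshold, fdr_threshold=fdr_threshold)


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# presence / absence


@dataclass
class PresencePartition:
    """Detection sets per factor level, with the exclusive/shared Venn split."""

    factor: str
    detect_floor: float
    detected: dict[str, set[str]] = field(default_factory=dict)
    exclusive: dict[str, set[str]] = field(default_factory=dict)
    shared: set[str] = field(default_factory=set)

    def counts(self) -> dict:
        return {
            "factor": self.factor,
            "detected": {k: len(v) for k, v in sorted(self.detected.items())},
            "exclusive": {k: len(v) for k, v in sorted(self.exclusive.items())},
            "shared": len(self.shared),
        }


def presence_partition(
    table: FeatureTable, factor: str = "organ", detect_floor: float = 10_000.0
) -> PresencePartition:
    """Partition features by detection across the levels of a design factor.

    A feature is detected in a level iff its intensity reaches
    ``detect_floor`` (inclusive) in at least one sample of that level;
    exclusive features are detected in exactly one level, shared in more
    than one.
    """
    groups = table.groups(factor)
    if len(groups) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    detected = {}
    for level, ids in sorted(groups.items()):
        mask = (table.intensities[ids] >= detect_floor).any(axis=1)
        detected[level] = set(table.intensities.index[mask])
    union = set().union(*detected.values())
    exclusive = {}
    for level, feats in detected.items():
        others = set().union(*(v for k, v in detected.items() if k != level))
        exclusive[level] = feats - others
    shared = union - set().union(*exclusive.values())
    return PresencePartition(
        factor=factor, detect_floor=detect_floor,
        detected=detected, exclusive=exclusive, shared=shared,
    )
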