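# Methods

This note records the models, rules and numerical choices behind
`phytometab`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Curation model

A raw mass feature table (one row per (m/z, retention-time) feature, one
column per injection) is reduced to a working table in four fixed stages.

**1. Identification gate.** A feature is kept when at least one line of
structural evidence holds — library MS/MS match score > 600, in-silico
fragmentation score > 800, or a top-confidence structure prediction — *and*
both spectral-quality gates hold: isotope-pattern fit mSigma < 30 and
|mass error| ≤ 2.5 ppm. Score thresholds are strict inequalities; the ppm
window is inclusive. A missing metric fails its own clause. The
evidence-OR / quality-AND reading is a deliberate choice: the alternative
(all clauses conjunctive) would discard library matches lacking in-silico
scores, which is not how tiered annotation evidence is used in practice.

**2. Imputation.** Within each organ × processing replicate cell: a feature
missing from *every* replicate is a biological zero there; a feature
missing from *some* replicates is a detection dropout and is imputed at
(its minimum observed intensity across all non-blank samples) − 1, i.e.
just below its own detection record. The per-feature minimum (rather than a
table-global minimum) keeps imputed values on the feature's own intensity
scale. A feature observed nowhere outside blanks has no record to sit below
and falls back to 0. The imputation group can be switched to the whole
non-blank table (`impute_scope="global"`).

**3. Noise removal**, in order: (a) features detected (≥ 10,000) in a blank
and in no experimental sample are blank-borne contaminants; (b) features
whose maximum blank intensity reaches their maximum experimental intensity
are blank-dominated (a median-vs-median rule is available via
`blank_rule="median"`; max is the default because a single high blank
injection is already disqualifying); (c) features whose maximum
experimental intensity is below 20,000 (strict) are noise. Each removal is
tallied per feature; dispositions partition the input.

**4. Blank subtraction.** Per feature, the median blank intensity is
subtracted from every experimental sample and negative remainders clamp to
0 (a negative background-corrected intensity has no physical meaning);
blank columns are then dropped.

The stage order (gate → impute → noise → subtract) is fixed; imputation
before noise removal means the blank rules see dropout-corrected values,
which only affects features at the detection margin.

## Annotation, novelty and NP-likeness

Structures are harmonized to (InChI, canonical SMILES, InChIKey) with
RDKit. The **connectivity skeleton** — the first 14 InChIKey characters —
is the canonical matching unit: LC-MS annotation rarely resolves
stereochemistry, so novelty assessment treats stereoisomers of a reported
compound as reported. Multi-label pathway/superclass classifications
collapse to a primary label plus a hybrid flag; the tie-break is
alphabetical by default (configurable priority list), and the reduction is
invariant under permutation of the input labels. Diversity tables count
(total, unreported) per label, suffixing "+ Hybrids" where any member was
multiply classified; structures that failed to parse have unknown novelty
and never count as unreported.

**NP-likeness** is a fragment-contribution score: each Morgan atom
environment (radius ≤ 2) contributes log10 of its Laplace-smoothed
frequency ratio between a natural-product corpus and a synthetic-compound
corpus; a molecule's score is the sum over its distinct fragments divided
by its heavy-atom count (×10 to spread the scale), with a soft logarithmic
clamp into [−5, 5]. The packaged model is trained at import time from two
small hand-assembled corpora (74 plant metabolites, 60 synthetic/
medicinal-chemistry structures) shipped as plain text. With corpora this
small the score is a coarse screening metric — its sign is meaningful, its
magnitude is not finely calibrated — and it is used only as metadata, never
as a filter.

## Chemospace

The default structural fingerprint is an 881-bit folded Morgan (radius 2)
binary keyset; MACCS-166 is available as an alternative dialect. Pairwise
similarity is the Tanimoto coefficient on bit sets; two empty fingerprints
are defined as identical (similarity 1) and logged. Clustering is
agglomerative (UPGMA by default; complete/single available) on the
dissimilarity 1 − Tanimoto, which for binary fingerprints is the Jaccard
distance and a proper metric. Newick export uses branch lengths equal to
parent-minus-child merge heights and a deterministic sibling order (the
subtree holding the lexicographically smallest leaf first), so identical
inputs yield byte-identical trees. Heatmap figures ship as data (the
distance matrix reordered by dendrogram leaves), not styled graphics.

## Comparative statistics

**Transform.** All per-feature models operate on log2(x + 1); the +1 keeps
post-curation zeros finite.

**PCA.** prcomp-style: features centred and scaled to unit variance,
singular value decomposition, n − 1 non-trivial components, explained
percentages summing to 100. Constant-variance features are dropped with a
warning. Component signs are fixed by making the largest-magnitude loading
positive.

**PERMANOVA.** One-way: SS_total = (1/n)·Σ_{i<j} d²_ij, SS_within summed
per group with 1/n_g weights, pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)),
R² = SS_between/SS_total. The p-value is permutational:
(#{F_perm ≥ F_obs} + 1)/(n_perm + 1) over seeded label permutations
(default n_perm = 999, so the smallest attainable p is 0.001), or the exact
rank over all n! permutations for n ≤ 9. The default distance is
Bray–Curtis on curated intensities; Euclidean on log2(x+1) is available,
and the choice is recorded in the result. The two-factor additive model
uses sequential (type-I) sums of squares via projection on the
Gower-centred inner-product matrix, terms in the stated order, free
permutation of rows. With semimetric distances (Bray–Curtis) the centred
matrix can have negative eigenvalues, so a term's R² can slightly exceed
what a Euclidean geometry would allow and the model total can marginally
exceed 100% when the residual is near zero; this is a property of
distance-based partitioning, not an implementation artefact.

**Moderated differential abundance.** Per feature, a two-sample contrast
with pooled variance s² on d = n₁+n₂−2 degrees of freedom. The variance
prior σ² ~ s₀²·d₀/χ²_{d₀} is fitted across features by the method of
moments on e = log s² − ψ(d/2) + log(d/2):

    E[e]  = log s₀² + ψ(d₀/2) − log(d₀/2)
    Var[e] = ψ′(d/2) + ψ′(d₀/2)

with ψ′ inverted by Newton iteration. When the observed spread of
log-variances does not exceed chi-square sampling noise the solution is
d₀ = ∞ (complete shrinkage, normal reference distribution). The posterior
variance (d₀s₀² + d s²)/(d₀+d) yields the moderated t with d₀+d degrees of
freedom; the d₀ → 0 limit reproduces the ordinary pooled t exactly.
Enrichment calls require |log2FC| > 1 and Benjamini–Hochberg FDR < 0.05;
log2FC is mean(group2) − mean(group1) with group order (root, seed) and
(extract, juice), i.e. positive = seed-/juice-enriched. Zero-variance
corner cases (all features constant) take the d₀ = ∞ path; a feature with
zero posterior variance and nonzero difference reports t = ±∞, p = 0
rather than crashing.

**Detection partitioning.** A feature is detected in a factor level iff its
intensity reaches 10,000 (inclusive — "not detected" means < 10,000) in at
least one sample of that level; exclusive features are detected in exactly
one level. Exclusive sets are disjoint and exclusive ∪ shared equals the
detected union on all inputs.

## Synthetic data

The generator emulates the assumed study design: 2 organs × 2 processing
methods × n_reps replicates (default 3) plus blanks (default 2), 540
features. Per feature, a log-normal baseline (ln-mean ln 1e5, ln-sd 1.0)
with multiplicative log-normal noise at CV 0.15. Planted structure:

* organ-enriched (15%) and method-enriched (10%) features, split evenly
  between directions, realised as a symmetric ±log2FC/2 fold on the
  affected cells (default log2FC = 3); their baselines are raised clear of
  the noise floor so the planted contrast — not the curation floor —
  decides their fate;
* contaminants (5%), alternately blank-only (high in blanks, undetectable
  in samples) and blank-dominated (detected in samples but exceeded by
  blanks with a guaranteed margin);
* sub-floor features (5%) capped below the 20,000 noise floor;
* missing values (5% of non-blank cells of non-artefact features);
* a novelty ground truth: each feature's unique structure is "previously
  reported" with probability 0.22 (roughly the share of genus-known
  metabolites such a survey finds), and the emitted reference set contains
  exactly those skeletons.

Structures are real plant metabolites from the packaged corpus first, then
generated unique linear C/O/N scaffolds; classification labels are drawn
from a packaged pathway/superclass vocabulary. Everything derives from one
seed; identical configs regenerate byte-identical files (the committed
80-feature test fixture is checksum-guarded against drift).

**What passing does not show.** The simulator draws independent features —
no correlated co-eluting adducts or in-source fragments, no retention-time
drift, no heteroscedastic intensity-dependent noise, no batch effects — and
its filler structures are chemically simpler than real metabolomes. Planted
effects are symmetric and well separated. Recovery results (precision and
recall ≥ 0.9 at log2FC = 3, CV 0.15, n = 3 per cell) therefore bound the
method's behaviour under its own assumptions, not under real-data
violations of them.

## Problem sizes and defaults

| parameter | default | why |
|---|---|---|
| noise_floor | 20,000 counts | maximum-intensity cutoff separating features from baseline noise |
| detect_floor | 10,000 counts | per-sample presence threshold (inclusive) |
| n_perm | 999 | p resolution 0.001 at seconds-scale runtime |
| n_features | 540 | metabolome-scale table; keeps full-pipeline runs in seconds |
| n_reps | 3 | smallest replication giving a usable within-group variance |
| lfc/fdr thresholds | 1 / 0.05 | conventional enrichment-call criteria |

The exact-enumeration PERMANOVA oracle is exercised at n ≤ 8 (8! = 40,320
permutations); hyperparameter-recovery simulations use 2,000 features × 10
seeds. These sizes were chosen so the whole suite runs in well under a
minute while keeping Monte-Carlo error far below the asserted tolerances.

## Known limitations

* Classification labels are consumed from input columns, not computed; the
  package does not re-implement NPClassifier/ClassyFire.
* Novelty assessment is as good as the supplied reference list; database
  snapshots are not reproducible bit-for-bit.
* The NP-likeness corpus is small; scores are screening metadata only.
* The 881-bit fingerprint is a folded circular keyset, not the CACTVS
  substructure key definition of the same length; within-package
  comparisons are consistent, but absolute Tanimoto values are not
  interchangeable with other dialects.
* Two-group contrasts and the additive two-factor distance model only; no
  interaction terms, dispersion tests, or general design matrices.
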