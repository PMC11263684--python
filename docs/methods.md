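# Methods

## Scope and model

The package implements a neoantigen prioritization cascade with four
stages: (1) enumeration of mutant 9/10-mer windows from protein-level
somatic variants with expression, anchor and binding prefilters; (2) a
binary immunogenicity classifier over candidate features; (3)
identification of putative tumor-reactive CD8+ TIL clonotypes from
single-cell expression + TCR data and a TCR–pMHC tier rule; (4)
entropy-based repertoire statistics. External neural predictors (pMHC
affinity, PRIME-style %rank, TCR–pMHC rank) enter only through an adapter
contract; a deterministic surrogate backend makes the whole cascade
runnable and testable offline.

## Enumeration and prefilters

Coordinates are 1-based, windows closed, and only full-length windows are
kept (no terminal padding). Altered residues are the positionwise
differences for length-preserving variants; for frameshifts the altered
region runs from the first changed residue to the translated stop, and for
in-frame indels from the end of the longest common prefix to the start of
the longest common suffix. Windows from length-changing variants carry no
wild-type counterpart: a same-length wild-type window at the same
coordinates does not exist, and wild-type-dependent features are imputed
(below). Duplicate mutant sequences from one variant collapse to a single
record retaining all window start positions; identical peptides from
*different* variants stay separate because provenance matters for
reporting.

Gate conventions, all configurable:

- VAF > 0 and read count > 10 are strict inequalities (a read count of 10
  fails).
- The TPM rule is stated as "TPM > log 0.4", which does not pin down a
  base; the default `TpmGate` reads it as log₁₀(TPM) > 0.4 (TPM ≳ 2.51)
  and both transform and threshold are configurable, with the chosen
  interpretation logged.
- Binding cutoffs (affinity ≤ 140 nM, PRIME %rank ≤ 0.847) are inclusive
  retention bounds; a peptide survives if any patient allele passes both,
  and the lowest-affinity passing allele is recorded.
- The position-2 anchor exclusion removes any peptide whose mutated
  residue set contains peptide position 2.

## Feature engine

The canonical 13 features are: mutant and wild-type affinity (nM),
agretopicity (wt/mt affinity ratio), an affinity-percentile proxy, PRIME
%rank, foreignness, dissimilarity-to-self, log₁₀(1+TPM), VAF,
log₁₀(1+reads), peptide length, Kyte–Doolittle hydrophobic fraction, and
the distance of the nearest mutated residue to the peptide center. The set
is configurable; downstream feature elimination re-selects among whatever
is supplied, so the pipeline's architecture (start wide, eliminate to an
optimal subset) does not depend on this exact list.

Foreignness and dissimilarity both use the logistic recognition map
`σ(k·(s − a))` with defaults k = 4.87, a = 26 (the published
recognition-potential constants), where `s` is the best *gapless* local
alignment score under BLOSUM62 — computed exactly by a per-diagonal
maximal-run scan (Smith–Waterman with infinite gap penalties).
Foreignness is the maximum over a reference epitope set (empty set → 0);
dissimilarity is 1 − the maximum over the self-proteome 9/10-mer index.
Missing wild-type windows impute wt_affinity = 50 000 nM (an effectively
non-binding sentinel) and agretopicity follows from it; the imputation is
flagged on the vector so a model can learn the frameshift pattern.

## Ensemble and operating point

The classifier defaults to gradient-boosted trees (60 stumps of depth 2),
with logistic regression as a config alternative; both are deterministic
given the seed. Backward elimination drops the feature with the smallest
importance (tree importance or |coefficient|) one at a time; each visited
subset is scored by grouped cross-validated PRAUC (GroupKFold by patient,
5 folds, reduced with a warning when there are fewer groups). The retained
subset maximizes CV PRAUC with ties broken toward fewer features. PRAUC is
computed by step-wise precision–recall integration at distinct score
thresholds (equivalent to average precision).

The decision threshold is chosen on out-of-fold scores: among distinct
observed score cuts whose F1 is within ε (default 10⁻⁹, i.e. exact
maximum) of the best F1, the cut with maximal sensitivity wins; remaining
ties resolve to the lowest cut. The prediction rule is inclusive
(score ≥ τ passes). ε is exposed because the verbal rule "highest
sensitivity while maintaining the highest F1" is not numerically
operationalized anywhere; exact-max is the most conservative reading.

## Single-cell TIL stage

QC keeps cells with ≥ min_genes detected genes and mitochondrial fraction
≤ max_mito; the CD8 gate is the strictest literal reading — raw
CD8A+CD8B counts > 0 and CD4 = 0 — with soft thresholds available.
Clustering is the standard scanpy chain (depth normalization to 10⁴,
log1p, PCA, kNN graph) followed by Louvain community detection via
igraph's multilevel algorithm with a seeded RNG, so labels are
reproducible. (scanpy's own `tl.louvain` wrapper needs the separate
`louvain` package; the igraph multilevel algorithm *is* Louvain, run here
directly on scanpy's connectivity graph.)

Subtype annotation scores each cluster by the mean z-scored log-normalized
expression of each subtype's markers and assigns the argmax, with a fixed
deterministic priority (exhausted > proliferating > effector > activated >
others) for exact ties. The human scheme uses: proliferating (MKI67,
TOP2A), exhausted (PDCD1, TIGIT, HAVCR2, LAG3, CTLA4), effector (GZMA,
GZMK, GZMH, PRF1, NKG7, TNF, GNLY, IFNG), activated (HLA-DR genes,
expanded to HLA-DRA/HLA-DRB1 since the family name does not name genes),
naive/memory (SELL, CCR7, IL7R), NK/γδ-like (TRGV9, TRDV2, KLRB1, KLRC3),
MAIT (TRAV1-2). The reactive union is
{proliferating, exhausted, effector, activated}. A mouse B16F10 preset
ships with activated/exhausted/non-exhausted-memory-like/proliferative/
NK-like subtypes and reactive union {exhausted, proliferative, activated}.

Clonotypes are unique productive CDR3β amino-acid sequences; a barcode
with conflicting β chains keeps the highest-UMI chain, and cells without a
β chain are dropped with a count.

## Repertoire indices

All logs are natural. Expansion is 1 − H/ln(#clones) over clone-size
frequencies, with stated conventions for the degenerate single-clone case
(singleton → 0, expanded → 1); these conventions intentionally break scale
invariance at exactly one clone. Migration is per-clone tissue entropy
normalized by ln(#tissues), aggregated as a clone-size-weighted mean.
Transition for a cluster pair is the size-weighted mean two-state entropy
over clones present in either cluster, symmetric by construction. Clone
overlap matches expanded spleen clones to tumor clones by exact CDR3β
identity; the spleen size filter defaults to > 2 (min size 3) because the
source material states the filter two inconsistent ways ("size 1 filtered
out" vs "size > 2 used"), and the stricter reading is the default, with
the other available by configuration.

## Tier rule and summaries

Pairing is exhaustive candidate × clonotype × allele, autologous by
design (candidates meet only their own patient's clonotypes and alleles).
Tier 1 iff the minimum TCR–pMHC rank < 0.05, strict, matching the
inclusive intent of raising the default 0.01 cutoff to 0.05. Hit-rate
percentages are rounded half-up to one decimal, which reproduces every
published summary ratio exactly (13/48 → 27.1, 17/70 → 24.3, 30/118 →
25.4, 7/8 → 87.5, 3/10 → 30.0).

## Surrogate backend

The surrogate is a pure function of a seeded SHA-256 hash of its inputs:
affinity log-uniform on [1, 50 000] nM, PRIME %rank uniform on [0, 100],
TCR rank uniform on [0, 1], with configurable "planted binders" forced to
rank 0.001 to give tier tests exact ground truth. It is version-stamped
and never silently substituted for a real backend: requesting an unwired
backend raises.

## Synthetic data

The generators emulate the statistical shape of the real inputs, not their
biology: negative-binomial counts (near-Poisson dispersion 0.1, UMI-like),
log-normal TPM, beta VAF, geometric clone sizes with heavier expansion in
reactive subtypes, and a logistic label model over standard-normal
features. The default TIL composition places 57.6% of cells in reactive
subtypes, mirroring the cohort this pipeline targets. Marker effect size
is measured in baseline standard deviations of log1p counts — the space
clustering operates in — via the delta method; the default of 5 sd
corresponds to "well-separated" programs. What passing tests show is that
the pipeline recovers planted structure of this kind; they do not show
robustness to batch effects, doublets, ambient RNA, dropout structure, or
continuous (non-discrete) cell states, none of which are simulated.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale as the package's own
choice of fixture size: feature-selection recovery at n = 400 with 2
signal + 8 noise features over 10–20 seeds, clustering at 450–700 cells
and ~70 genes, tier fixtures at ≤ 10 candidates × ≤ 30 clonotypes.
Ties everywhere break deterministically (lowest threshold, fixed subtype
priority, lexicographic clone ids). Degenerate inputs raise rather than
guess: single-class labels, all-identical scores, empty clone lists, empty
proteome indices.

## Known limitations

- The exact published 13-feature list and the QC thresholds behind the
  cohort cell counts are in supplementary material not reproduced here;
  the canonical feature set and QC defaults are documented choices, not
  claimed matches.
- Real predictor backends are contract-only in this repository; results
  with the surrogate quantify pipeline mechanics, not predictive accuracy
  against experimental immunogenicity.
- Inframe-indel windows are treated like frameshift-novel windows for
  wild-type-dependent features whenever no same-length aligned wild-type
  window exists.
- Expansion comparisons between reactive and remaining cells are reported
  as a descriptive contrast of indices; no parametric test is implied.
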