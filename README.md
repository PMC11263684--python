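# vacinus

Neoantigen prioritization for personalized cancer vaccines: from annotated
somatic mutations and expression data to candidate 9/10-mer neoepitopes,
through a peptide–MHC (pMHC) immunogenicity ensemble, to a
TCR-repertoire-aware tier classification driven by putative tumor-reactive
CD8+ tumor-infiltrating lymphocyte (TIL) clonotypes.

The package is for computational immunologists building or evaluating
neoantigen selection pipelines. It implements the full decision cascade as
a tested library plus a thin `vacinus` CLI, with a deterministic surrogate
predictor backend and synthetic-data generators so every stage runs and is
testable offline.

## The method

**1. Candidate enumeration and prefilters.** Protein-level variants
(missense, in-frame indel, frameshift) are expanded into every mutant
window of length 9–10 containing ≥1 altered residue. Candidates are
filtered by:

- expression: VAF > 0, transcript read count > 10, and a TPM gate
  (default log₁₀ TPM > 0.4);
- MHC anchor: any peptide mutated at position 2 (the dominant class-I
  binding anchor) is excluded;
- binding: predicted affinity ≤ 140 nM and PRIME-style %rank ≤ 0.847 for
  at least one patient HLA allele.

**2. pMHC immunogenicity ensemble.** Each candidate is represented by 13
features (mutant/wild-type affinity, agretopicity `wt_aff/mt_aff`,
foreignness and dissimilarity-to-self through the logistic recognition
model `1/(1+e^{-k(s-a)})` over gapless BLOSUM62 alignment scores `s`,
expression and sequence features). A gradient-boosted classifier is trained
with recursive feature elimination maximizing grouped cross-validated
PRAUC, and the operating threshold τ is the score cut with the highest
sensitivity among cuts attaining the maximal F1 (prediction passes iff
score ≥ τ).

**3. TCR tier assignment.** CD8+ TILs from single-cell RNA/TCR data are
QC'd, gated (CD8⁺CD4⁻), Louvain-clustered, and annotated by marker
scores; cells in exhausted, proliferating, activated or effector clusters
form the putative tumor-reactive union, and their unique CDR3β clonotypes
the reactive repertoire. Every pMHC-passing candidate is scored against
every reactive clonotype; a candidate is **tier 1** iff its minimum
TCR–pMHC rank < 0.05.

**4. Repertoire statistics.** STARTRAC-style entropy indices quantify the
response: expansion `1 − H/ln(#clones)` over clone sizes, per-clone tissue
migration `H/ln(#tissues)`, pairwise cluster transition indices, and
spleen–tumor clone overlap (expanded spleen clones, size > 2, matched to
tumor clones by exact CDR3β identity).

## Worked example

```python
from vacinus import *
from vacinus.peptides import VariantRecord, VariantClass

wt = "ARNDCQEGHILKMFPSTWYVARNDCQEGHI"
mt = wt[:9] + "W" + wt[10:]                      # missense at position 10
v = VariantRecord("v1", "GENE1", VariantClass.MISSENSE, 10, wt, mt,
                  vaf=0.3, read_count=25, tpm=10.0)
cands = enumerate_windows(v)                     # 19 windows (9 nine-mers + 10 ten-mers)
kept, log = filter_anchor(cands)                 # removes the 2 windows mutated at position 2
print(len(cands), log.removed)                   # 19 {'anchor_position_2': 2}

print(expansion_index([2, 1, 1]))                # 0.0536... (near-flat repertoire)
print(migration_index({"c": {"tumor": 3, "spleen": 1}})[0]["c"])  # 0.8113...
```

Output:

```
19 {'anchor_position_2': 2}
0.05360536964281404
0.8112781244591328
```

19 candidate windows cover the mutated residue; exactly two place it on the
position-2 anchor and are dropped. A repertoire of clone sizes (2,1,1) is
barely clonal (expansion index 0.054); a clone split 3:1 between tumor and
spleen has migration entropy 0.81 of the maximum.

Model fitting is statsmodels-style:

```python
from vacinus.ensemble import ImmunogenicityModel
from vacinus.simulate import LabeledFeatureSpec, make_labeled_features

X, y, groups, _ = make_labeled_features(LabeledFeatureSpec(seed=0, n=400))
res = ImmunogenicityModel(X, y, groups).fit(seed=0)
print(res.summary())
```

which prints the selected feature subset, the decision threshold and the
cross-validated PRAUC/sensitivity/PPV/F1 table.

## Layout

- `vacinus.peptides` — variant → window enumeration and the prefilter cascade
- `vacinus.adapters` — predictor contract, score cache, deterministic surrogate
- `vacinus.features` — the 13-feature engine (alignment, expression, sequence)
- `vacinus.ensemble` — `ImmunogenicityModel` / `ImmunogenicityResults` (RFE + τ)
- `vacinus.til` — single-cell QC, clustering, subtype annotation, clonotypes
- `vacinus.repertoire` — expansion / migration / transition / overlap
- `vacinus.tiers` — tier 1 assignment and hit-rate summaries
- `vacinus.simulate` — synthetic fixtures with planted ground truth
- `vacinus.io`, `vacinus.cli` — file formats and the `vacinus` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
limitations.
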