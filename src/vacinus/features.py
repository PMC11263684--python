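"""Candidate-level feature engineering for the immunogenicity ensemble.

Computes the canonical 13-feature representation of a candidate neoepitope:
binding features (mutant/wild-type affinity, agretopicity, ranks), the
logistic recognition-model features (foreignness against a reference epitope
set, dissimilarity against the self-proteome), expression features and simple
sequence features. The feature set is configurable; recursive feature
elimination downstream re-selects among whatever is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .adapters import PmhcScore
from .peptides import CandidatePeptide

#: Sentinel affinity for missing wild-type counterparts (frameshift-novel
#: windows): an effectively non-binding 50000 nM.
WT_AFFINITY_SENTINEL_NM = 50000.0

#: Logistic recognition-model constants (steepness, midpoint alignment score).
LOGISTIC_K = 4.87
LOGISTIC_A = 26.0

CANONICAL_FEATURES = (
    "mt_affinity_nM",
    "wt_affinity_nM",
    "agretopicity",
    "mt_affinity_rank",
    "prime_rank",
    "foreignness",
    "dissimilarity_to_self",
    "tpm_log",
    "vaf",
    "read_count_log",
    "peptide_length",
    "hydrophobicity_fraction",
    "anchor_distance",
)

FEATURE_SCHEMA_VERSION = "1"

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

# Kyte-Doolittle hydropathy > 0
_HYDROPHOBIC = set("AVILMFC")


def agretopicity(mt_aff: float, wt_aff: float) -> float:
    """Differential agretopicity: wt/mt affinity ratio (nM); > 1 means the
    mutant binds MHC better than its wild-type counterpart."""
    if mt_aff <= 0 or wt_aff <= 0:
        raise ValueError("affinities must be positive")
    return wt_aff / mt_aff


def gapless_alignment_score(a: str, b: str) -> float:
    """Best gapless local alignment score of two peptides under BLOSUM62.

    Equivalent to Smith-Waterman with infinite gap penalties: for each
    diagonal offset, the maximal-sum contiguous run of pairwise substitution
    scores (Kadane's scan). Returns 0 when no positive-scoring run exists.
    """
    best = 0.0
    la, lb = len(a), len(b)
    for off in range(-(lb - 1), la):
        run = 0.0
        i = max(0, off)
        j = i - off
        while i < la and j < lb:
            run = max(0.0, run + _BLOSUM62[a[i], b[j]])
            best = max(best, run)
            i += 1
            j += 1
    return best


def _recognition_logistic(score: float, k: float, a: float) -> float:
    return 1.0 / (1.0 + math.exp(-k * (score - a)))


def foreignness(
    peptide: str,
    epitope_set: Sequence[str],
    k: float = LOGISTIC_K,
    a: float = LOGISTIC_A,
) -> float:
    """Similarity of a peptide to known epitopes through the logistic
    recognition model: max over epitopes of logistic(k*(score - a)) where
    score is the best gapless BLOSUM62 alignment. Empty set -> 0."""
    if not epitope_set:
        return 0.0
    return max(
        _recognition_logistic(gapless_alignment_score(peptide, e), k, a)
        for e in epitope_set
    )


class SelfProteomeIndex:
    """k-mer index over a self proteome at lengths {9,10}.

    Desk-scale by design: the index is an in-memory set of windows, and
    dissimilarity queries scan the top-N best-aligning self peptides
    exhaustively (N caps work for large proteomes; alignment is the cost).
    """

    def __init__(self, proteins: Mapping[str, str], lengths: Iterable[int] = (9, 10)):
        self.kmers: list[str] = sorted(
            {
                seq[i : i + L]
                for seq in proteins.values()
                for L in lengths
                for i in range(len(seq) - L + 1)
            }
        )
        if not self.kmers:
            raise ValueError("self-proteome index is empty")

    def best_scores(self, peptide: str, top_n: int) -> list[float]:
        scores = sorted(
            (gapless_alignment_score(peptide, m) for m in self.kmers), reverse=True
        )
        return scores[:top_n]


def dissimilarity_to_self(
    peptide: str,
    self_index: SelfProteomeIndex,
    k: float = LOGISTIC_K,
    a: float = LOGISTIC_A,
    top_n: int = 10,
) -> float:
    """One minus the logistic recognition similarity to the closest self
    peptides; ~0 for peptides present verbatim in the proteome."""
    best = max(
        _recognition_logistic(s, k, a) for s in self_index.best_scores(peptide, top_n)
    )
    return 1.0 - best


def hydrophobicity_fraction(peptide: str) -> float:
    """Fraction of residues with positive Kyte-Doolittle hydropathy."""
    return sum(c in _HYDROPHOBIC for c in peptide) / len(peptide)


def anchor_distance(peptide_length: int, mut_positions: frozenset[int]) -> float:
    """Distance from the nearest mutated residue to the peptide center."""
    center = (peptide_length + 1) / 2.0
    return min(abs(p - center) for p in mut_positions)


@dataclass
class FeatureVector:
    peptide_id: str
    features: dict[str, float]
    mask: frozenset[str] = field(default_factory=frozenset)
    imputed: frozenset[str] = field(default_factory=frozenset)


def build_features(
    candidates: Sequence[CandidatePeptide],
    mt_scores: Mapping[tuple[str, str], PmhcScore],
    wt_scores: Mapping[tuple[str, str], PmhcScore],
    epitope_set: Sequence[str] = (),
    self_index: SelfProteomeIndex | None = None,
    affinity_rank_fn=None,
) -> list[FeatureVector]:
    """Assemble one 13-feature vector per candidate.

    ``mt_scores``/``wt_scores`` are keyed by (sequence, allele). Candidates
    without a wild-type counterpart (frameshift-novel windows) get the
    50000 nM wild-type sentinel, with the imputation recorded on the vector.
    ``affinity_rank_fn(affinity_nM)`` maps affinity to a percentile-style
    rank; the default is a log-affinity percentile proxy on [0,100].
    """
    if affinity_rank_fn is None:
        # log-affinity mapped to [0,100]; 1 nM -> 0, 50000 nM -> 100
        affinity_rank_fn = lambda aff: 100.0 * math.log10(max(aff, 1.0)) / 4.69897

    vectors = []
    for cand in candidates:
        if cand.allele is None:
            raise ValueError(f"{cand.peptide_id}: allele not assigned")
        mt = mt_scores[(cand.mt_seq, cand.allele)]
        imputed: set[str] = set()
        if cand.wt_seq is not None and (cand.wt_seq, cand.allele) in wt_scores:
            wt_aff = wt_scores[(cand.wt_seq, cand.allele)].affinity_nM
        else:
            wt_aff = WT_AFFINITY_SENTINEL_NM
            imputed |= {"wt_affinity_nM", "agretopicity"}
        feats = {
            "mt_affinity_nM": mt.affinity_nM,
            "wt_affinity_nM": wt_aff,
            "agretopicity": agretopicity(mt.affinity_nM, wt_aff),
            "mt_affinity_rank": affinity_rank_fn(mt.affinity_nM),
            "prime_rank": mt.prime_rank,
            "foreignness": foreignness(cand.mt_seq, epitope_set),
            "dissimilarity_to_self": (
                dissimilarity_to_self(cand.mt_seq, self_index)
                if self_index is not None
                else 1.0
            ),
            "tpm_log": math.log10(1.0 + cand.tpm),
            "vaf": cand.vaf,
            "read_count_log": math.log10(1.0 + cand.read_count),
            "peptide_length": float(len(cand.mt_seq)),
            "hydrophobicity_fraction": hydrophobicity_fraction(cand.mt_seq),
            "anchor_distance": anchor_distance(len(cand.mt_seq), cand.mut_positions),
        }
        for name, value in feats.items():
            if not np.isfinite(value):
                raise ValueError(
                    f"non-finite feature {name!r} for candidate {cand.peptide_id}"
                )
        vectors.append(
            FeatureVector(
                peptide_id=cand.peptide_id,
                features=feats,
                mask=frozenset(CANONICAL_FEATURES),
                imputed=frozenset(imputed),
            )
        )
    return vectors


def feature_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Feature vectors as a DataFrame in canonical column order."""
    df = pd.DataFrame([v.features for v in vectors], index=[v.peptide_id for v in vectors])
    return df[[c for c in CANONICAL_FEATURES if c in df.columns]]
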