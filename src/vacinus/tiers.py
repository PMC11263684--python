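"""TCR-repertoire-aware tier assignment and cohort hit-rate summaries.

Every candidate that survived the pMHC stage is paired with the putative
tumor-reactive clonotype repertoire of its own patient; the TCR-pMHC rank is
scored for every candidate x clonotype x allele triple and the minimum over
pairings decides the tier: tier 1 iff min_rank < cutoff (strict), default
cutoff 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .adapters import SurrogateBackend, score_tcr
from .peptides import CandidatePeptide
from .til import Clonotype

DEFAULT_TCR_CUTOFF = 0.05


@dataclass
class TierRecord:
    peptide_id: str
    mt_seq: str
    min_rank: float
    best_clone: str | None
    tier: str  # "tier1" | "nontier1"


@dataclass
class TierReport:
    records: list[TierRecord]
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "peptide_id": r.peptide_id,
                    "mt_seq": r.mt_seq,
                    "min_rank": r.min_rank,
                    "best_clone": r.best_clone,
                    "tier": r.tier,
                }
                for r in self.records
            ]
        )


def assign_tiers(
    candidates: Sequence[CandidatePeptide],
    clonotypes: Sequence[Clonotype],
    alleles: Sequence[str],
    backend: SurrogateBackend,
    cutoff: float = DEFAULT_TCR_CUTOFF,
) -> TierReport:
    """Exhaustively score candidate x clonotype x allele and classify.

    min_rank is the minimum TCR-pMHC rank over all pairings of a candidate;
    tier 1 iff min_rank < cutoff. An empty clonotype set yields all
    nontier 1 with a warning (min_rank 1.0, no best clone).
    """
    records = []
    if not clonotypes:
        warnings.warn("empty clonotype set: all candidates assigned nontier1")
    for cand in candidates:
        cand_alleles = [cand.allele] if cand.allele else list(alleles)
        best_rank, best_clone = 1.0, None
        if clonotypes:
            triples = [
                (clone.cdr3b_aa, cand.mt_seq, allele)
                for clone in clonotypes
                for allele in cand_alleles
            ]
            scores = score_tcr(triples, backend)
            by_clone = [
                (s.rank, clone.clone_id)
                for clone, chunk in zip(
                    clonotypes,
                    [
                        scores[i : i + len(cand_alleles)]
                        for i in range(0, len(scores), len(cand_alleles))
                    ],
                )
                for s in chunk
            ]
            best_rank, best_clone = min(by_clone)
        records.append(
            TierRecord(
                peptide_id=cand.peptide_id,
                mt_seq=cand.mt_seq,
                min_rank=best_rank,
                best_clone=best_clone,
                tier="tier1" if best_rank < cutoff else "nontier1",
            )
        )
    return TierReport(records=records, cutoff=cutoff)


def round_half_up_pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with round-half-up at ``decimals`` places, matching how
    printed summary percentages are conventionally rounded."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator in percentage")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def summarize_hit_rates(
    tiers: Mapping[str, str],
    labels: Mapping[str, bool],
    patients: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-tier and overall immunogenicity hit rates.

    ``tiers`` maps candidate id -> tier; ``labels`` maps candidate id ->
    immunogenic (candidates without a label are excluded and counted);
    ``patients`` optionally maps candidate id -> patient id, enabling the
    per-patient response indicator (>=1 immunogenic candidate) and cohort
    response rate. Percentages are round-half-up to one decimal.
    """
    if not tiers:
        raise ValueError("empty tier report")
    labeled = {c: t for c, t in tiers.items() if c in labels}
    n_unlabeled = len(tiers) - len(labeled)
    rows = []
    groups: dict[str, list[str]] = {"overall": list(labeled)}
    for c, t in labeled.items():
        groups.setdefault(t, []).append(c)
    for name in sorted(groups):
        cands = groups[name]
        n = len(cands)
        pos = sum(bool(labels[c]) for c in cands)
        rows.append(
            {
                "group": name,
                "n": n,
                "n_immunogenic": pos,
                "hit_rate_pct": round_half_up_pct(pos, n) if n else float("nan"),
            }
        )
    if patients is not None:
        by_patient: dict[str, bool] = {}
        for c in labeled:
            p = patients[c]
            by_patient[p] = by_patient.get(p, False) or bool(labels[c])
        responders = sum(by_patient.values())
        rows.append(
            {
                "group": "patients_responding",
                "n": len(by_patient),
                "n_immunogenic": responders,
                "hit_rate_pct": round_half_up_pct(responders, len(by_patient)),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_unlabeled_excluded"] = n_unlabeled
    return df
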