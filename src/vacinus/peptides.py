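"""Mutant peptide enumeration and prefiltering.

Turns protein-level somatic variants into candidate 9/10-mer neoepitopes and
applies the cascade of prefilters used for candidate selection: expression
gates (VAF, transcript read support, TPM), exclusion of mutations at the
position-2 MHC anchor, and peptide-MHC binding cutoffs (predicted affinity and
PRIME-style %rank).

Coordinates are 1-based throughout; window intervals are closed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Default retention cutoffs for the binding prefilter.
DEFAULT_AFFINITY_CUTOFF_NM = 140.0
DEFAULT_PRIME_CUTOFF = 0.847


class VariantClass(str, Enum):
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    FRAMESHIFT = "frameshift"


@dataclass(frozen=True)
class VariantRecord:
    """A protein-level somatic variant with expression attributes.

    ``protein_pos`` is the 1-based position of the first altered residue in
    the wild-type protein. ``mt_protein`` is the full mutant protein; for
    frameshifts it is the translation up to (not including) the novel stop.
    """

    variant_id: str
    gene: str
    variant_class: VariantClass
    protein_pos: int
    wt_protein: str
    mt_protein: str
    vaf: float
    read_count: int
    tpm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"{self.variant_id}: VAF {self.vaf} outside [0,1]")
        if self.read_count < 0:
            raise ValueError(f"{self.variant_id}: negative read count")
        if self.tpm < 0:
            raise ValueError(f"{self.variant_id}: negative TPM")
        if not (1 <= self.protein_pos <= len(self.wt_protein)):
            raise ValueError(
                f"{self.variant_id}: protein_pos {self.protein_pos} outside "
                f"wild-type protein of length {len(self.wt_protein)}"
            )


@dataclass
class CandidatePeptide:
    """One mutant 9/10-mer with its wild-type counterpart and provenance."""

    peptide_id: str
    mt_seq: str
    wt_seq: str | None
    mut_positions: frozenset[int]  # 1-based within the peptide
    source_variant: str
    gene: str = ""
    windows: tuple[int, ...] = ()  # 1-based start positions in mt_protein
    allele: str | None = None
    vaf: float = 0.0
    read_count: int = 0
    tpm: float = 0.0
    affinity_nM: float | None = None
    prime_rank: float | None = None

    def __len__(self) -> int:
        return len(self.mt_seq)


@dataclass
class FilterLog:
    """Per-rule removal counts emitted by each filter stage."""

    stage: str
    n_in: int
    n_out: int
    removed: dict[str, int] = field(default_factory=dict)


def _altered_region(variant: VariantRecord) -> tuple[int, int]:
    """Closed 1-based interval of altered residues in the mutant protein.

    Missense/MNV: the set of differing positions is taken directly. For
    length-changing variants the altered region runs from the end of the
    longest common prefix to (frameshift) the new stop or (inframe indel) the
    start of the longest common suffix.
    """
    wt, mt = variant.wt_protein, variant.mt_protein
    if variant.variant_class is VariantClass.FRAMESHIFT or len(wt) != len(mt):
        lo = variant.protein_pos
        if variant.variant_class is VariantClass.FRAMESHIFT:
            return lo, len(mt)
        # inframe indel: common suffix bounds the junction on the right
        suffix = 0
        while (
            suffix < min(len(wt), len(mt)) - (lo - 1)
            and wt[len(wt) - 1 - suffix] == mt[len(mt) - 1 - suffix]
        ):
            suffix += 1
        hi = max(lo, len(mt) - suffix)
        return lo, min(hi, len(mt))
    return variant.protein_pos, len(mt)


def _diff_positions(variant: VariantRecord) -> set[int]:
    """1-based mutant-protein positions that differ from wild type."""
    wt, mt = variant.wt_protein, variant.mt_protein
    if len(wt) == len(mt) and variant.variant_class is not VariantClass.FRAMESHIFT:
        return {i + 1 for i in range(len(mt)) if wt[i] != mt[i]}
    lo, hi = _altered_region(variant)
    return set(range(lo, hi + 1))


def enumerate_windows(
    variant: VariantRecord, lengths: Iterable[int] = (9, 10)
) -> list[CandidatePeptide]:
    """Enumerate every mutant window of the requested lengths covering >=1
    altered residue.

    For missense variants the aligned wild-type window is attached; windows
    from length-changing variants (frameshift, inframe indel) have no
    wild-type counterpart. Windows truncated by the protein termini are
    omitted. Duplicate mutant sequences from the same variant collapse to one
    record that retains all window start positions.

    Raises ``ValueError`` on non-canonical residues; an identical mutant
    protein yields an empty list.
    """
    lengths = sorted(set(lengths))
    if not set(lengths) <= set(range(8, 12)):
        raise ValueError(f"window lengths {lengths} outside 8..11")
    for label, seq in (("wt", variant.wt_protein), ("mt", variant.mt_protein)):
        bad = set(seq) - CANONICAL_AA
        if bad:
            raise ValueError(
                f"{variant.variant_id}: non-canonical residue(s) {sorted(bad)} "
                f"in {label} protein"
            )
    diffs = _diff_positions(variant)
    if not diffs:
        warnings.warn(
            f"{variant.variant_id}: mutant protein identical to wild type; "
            "no windows enumerated"
        )
        return []

    same_length = (
        len(variant.wt_protein) == len(variant.mt_protein)
        and variant.variant_class is not VariantClass.FRAMESHIFT
    )
    mt = variant.mt_protein
    by_seq: dict[tuple[str, str | None], CandidatePeptide] = {}
    for L in lengths:
        for start in range(1, len(mt) - L + 2):  # 1-based, full windows only
            window = set(range(start, start + L))
            hit = window & diffs
            if not hit:
                continue
            mt_seq = mt[start - 1 : start - 1 + L]
            wt_seq = (
                variant.wt_protein[start - 1 : start - 1 + L] if same_length else None
            )
            mut_positions = frozenset(p - start + 1 for p in hit)
            key = (mt_seq, wt_seq)
            if key in by_seq:
                by_seq[key].windows += (start,)
            else:
                by_seq[key] = CandidatePeptide(
                    peptide_id=f"{variant.variant_id}:{L}:{start}",
                    mt_seq=mt_seq,
                    wt_seq=wt_seq,
                    mut_positions=mut_positions,
                    source_variant=variant.variant_id,
                    gene=variant.gene,
                    windows=(start,),
                    vaf=variant.vaf,
                    read_count=variant.read_count,
                    tpm=variant.tpm,
                )
    return list(by_seq.values())


def filter_anchor(
    peptides: Sequence[CandidatePeptide],
) -> tuple[list[CandidatePeptide], FilterLog]:
    """Drop peptides whose mutation falls on the position-2 binding anchor."""
    kept = [p for p in peptides if 2 not in p.mut_positions]
    log = FilterLog(
        stage="anchor",
        n_in=len(peptides),
        n_out=len(kept),
        removed={"anchor_position_2": len(peptides) - len(kept)},
    )
    return kept, log


@dataclass(frozen=True)
class TpmGate:
    """Configurable expression gate on TPM.

    The default reads the TPM rule as log10(TPM) > 0.4 (TPM > ~2.51); both
    the transform and the threshold are configurable because the rule's base
    is ambiguous in its source.
    """

    threshold: float = 0.4
    transform: Callable[[float], float] = math.log10
    name: str = "log10(TPM) > 0.4"

    def __call__(self, tpm: float) -> bool:
        if tpm <= 0:
            return False
        return self.transform(tpm) > self.threshold


def filter_expression(
    peptides: Sequence[CandidatePeptide],
    vaf_min: float = 0.0,
    read_min: int = 10,
    tpm_gate: TpmGate | None = None,
) -> tuple[list[CandidatePeptide], FilterLog]:
    """Expression prefilter: VAF > vaf_min, read_count > read_min (both
    strict), and the TPM gate. Emits per-rule removal counts."""
    gate = tpm_gate or TpmGate()
    removed = {"vaf": 0, "read_count": 0, "tpm": 0}
    kept = []
    for p in peptides:
        if p.vaf is None or p.read_count is None or p.tpm is None:
            raise ValueError(f"{p.peptide_id}: missing expression attribute")
        if not p.vaf > vaf_min:
            removed["vaf"] += 1
        elif not p.read_count > read_min:
            removed["read_count"] += 1
        elif not gate(p.tpm):
            removed["tpm"] += 1
        else:
            kept.append(p)
    log = FilterLog(
        stage="expression", n_in=len(peptides), n_out=len(kept), removed=removed
    )
    return kept, log


def filter_binding(
    peptides: Sequence[CandidatePeptide],
    affinity_nM: Mapping[tuple[str, str], float],
    prime_rank: Mapping[tuple[str, str], float],
    alleles: Sequence[str],
    aff_cut: float = DEFAULT_AFFINITY_CUTOFF_NM,
    prime_cut: float = DEFAULT_PRIME_CUTOFF,
) -> tuple[list[CandidatePeptide], FilterLog]:
    """Binding prefilter: keep a peptide if for >=1 patient allele the
    predicted affinity is <= aff_cut nM AND the PRIME %rank is <= prime_cut.

    Both cutoffs are inclusive retention bounds. The surviving record carries
    the best passing allele (lowest affinity) and its scores. A missing score
    for any (peptide, allele) pair raises ``KeyError`` naming the pair.
    """
    kept = []
    for p in peptides:
        best: tuple[float, float, str] | None = None
        for allele in alleles:
            key = (p.mt_seq, allele)
            if key not in affinity_nM or key not in prime_rank:
                raise KeyError(f"missing predictor score for {key}")
            aff, pr = affinity_nM[key], prime_rank[key]
            if aff <= aff_cut and pr <= prime_cut:
                if best is None or aff < best[0]:
                    best = (aff, pr, allele)
        if best is not None:
            q = replace(p, allele=best[2], affinity_nM=best[0], prime_rank=best[1])
            kept.append(q)
    log = FilterLog(
        stage="binding",
        n_in=len(peptides),
        n_out=len(kept),
        removed={"no_passing_allele": len(peptides) - len(kept)},
    )
    return kept, log
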