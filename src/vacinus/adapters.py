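"""Uniform adapters for the external binding predictors.

The workflow consumes three kinds of external scores: peptide-MHC binding
affinity (nM), a PRIME-style immunogenicity %rank (percentile, lower =
better) and a TCR-pMHC binding rank in [0,1] (lower = stronger). Real
backends (MHCflurry, PRIME, pMTnet) are heavyweight neural models invoked
out of process through a JSON request/response contract; this module defines
the contract, an in-memory/on-disk score cache, and a deterministic
*surrogate* backend so the full pipeline runs and is testable offline.

The surrogate is a pure function of a seeded hash of its inputs: identical
queries always return bit-identical scores, and a configurable list of
"planted binders" lets downstream tier tests carry known ground truth.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SURROGATE_VERSION = "surrogate-1"
PLANTED_BINDER_RANK = 0.001

_ALLELE_RE = re.compile(r"^(HLA-[ABC]\*\d{2}:\d{2}|H-?2-?[KDL][bdk])$", re.IGNORECASE)
_CDR3_RE = re.compile(r"^C[ACDEFGHIKLMNPQRSTVWY]+[FW]$")


@dataclass(frozen=True)
class PmhcScore:
    peptide: str
    allele: str
    affinity_nM: float
    prime_rank: float  # percentile in [0,100], lower = better

    def __post_init__(self) -> None:
        if self.affinity_nM <= 0:
            raise ValueError("affinity must be positive")
        if not (0.0 <= self.prime_rank <= 100.0):
            raise ValueError("prime_rank outside [0,100]")


@dataclass(frozen=True)
class TcrPmhcScore:
    cdr3b: str
    peptide: str
    allele: str
    rank: float  # [0,1], lower = stronger predicted binding

    def __post_init__(self) -> None:
        if not (0.0 <= self.rank <= 1.0):
            raise ValueError("rank outside [0,1]")


def validate_allele(allele: str) -> None:
    if not _ALLELE_RE.match(allele):
        raise ValueError(f"malformed HLA/H-2 allele name: {allele!r}")


def is_canonical_cdr3(cdr3b: str) -> bool:
    """Canonical CDR3beta: starts with C, ends with F/W (warn-only check)."""
    return bool(_CDR3_RE.match(cdr3b))


def _unit_hash(seed: int, *parts: str) -> float:
    """Deterministic uniform in [0,1) from a seeded SHA-256 of the parts."""
    h = hashlib.sha256(("%d|" % seed + "|".join(parts)).encode()).digest()
    return int.from_bytes(h[:8], "big") / 2**64


@dataclass
class SurrogateBackend:
    """Deterministic stand-in predictor for offline runs and tests.

    Affinity is log-uniform in [1, 50000] nM and the PRIME %rank uniform in
    [0,100], both pure functions of (seed, peptide, allele). TCR ranks are
    uniform in [0,1] except for planted (cdr3b, peptide) pairs, which are
    forced to ``PLANTED_BINDER_RANK``.
    """

    seed: int = 0
    planted_binders: set[tuple[str, str]] = field(default_factory=set)
    name: str = "surrogate"
    version: str = SURROGATE_VERSION

    def pmhc(self, peptide: str, allele: str) -> PmhcScore:
        u1 = _unit_hash(self.seed, "aff", peptide, allele)
        u2 = _unit_hash(self.seed, "prime", peptide, allele)
        affinity = 10.0 ** (u1 * 4.69897)  # log10(50000) ~ 4.69897
        return PmhcScore(peptide, allele, affinity, u2 * 100.0)

    def tcr(self, cdr3b: str, peptide: str, allele: str) -> TcrPmhcScore:
        if (cdr3b, peptide) in self.planted_binders:
            return TcrPmhcScore(cdr3b, peptide, allele, PLANTED_BINDER_RANK)
        u = _unit_hash(self.seed, "tcr", cdr3b, peptide, allele)
        return TcrPmhcScore(cdr3b, peptide, allele, u)


class ScoreCache:
    """Keyed score store, optionally persisted as a TSV table.

    Keys are (peptide, allele, cdr3b-or-empty, backend, version); a cache hit
    returns the value recorded at computation time unchanged.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self._store: dict[tuple[str, str, str, str, str], dict] = {}
        if self.path and self.path.exists():
            df = pd.read_csv(self.path, sep="\t", dtype=str, keep_default_na=False)
            for row in df.itertuples(index=False):
                key = (row.peptide, row.allele, row.cdr3b, row.backend, row.version)
                self._store[key] = {
                    "affinity_nM": float(row.affinity_nM) if row.affinity_nM else None,
                    "prime_rank": float(row.prime_rank) if row.prime_rank else None,
                    "rank": float(row.rank) if row.rank else None,
                }

    def get(self, key):
        return self._store.get(key)

    def put(self, key, value: dict) -> None:
        self._store[key] = value

    def flush(self) -> None:
        if not self.path:
            return
        rows = [
            {
                "peptide": k[0],
                "allele": k[1],
                "cdr3b": k[2],
                "backend": k[3],
                "version": k[4],
                **{f: "" if v.get(f) is None else repr(v[f])
                   for f in ("affinity_nM", "prime_rank", "rank")},
            }
            for k, v in self._store.items()
        ]
        pd.DataFrame(rows).to_csv(self.path, sep="\t", index=False)


def get_backend(name: str, seed: int = 0, **kwargs) -> SurrogateBackend:
    """Resolve a backend by name.

    Only the surrogate runs in-process. Asking for a real backend that is not
    wired up raises — there is never a silent fallback to the surrogate.
    """
    if name == "surrogate":
        return SurrogateBackend(seed=seed, **kwargs)
    raise RuntimeError(
        f"backend {name!r} is not available in this installation; "
        "real predictors are invoked through the external JSON contract"
    )


def score_pmhc(
    pairs: Sequence[tuple[str, str]],
    backend: SurrogateBackend,
    cache: ScoreCache | None = None,
) -> list[PmhcScore]:
    """Score peptide-allele pairs, one output per input, order preserved."""
    out = []
    for peptide, allele in pairs:
        validate_allele(allele)
        if not (8 <= len(peptide) <= 11):
            raise ValueError(f"peptide {peptide!r} length outside 8..11")
        key = (peptide, allele, "", backend.name, backend.version)
        hit = cache.get(key) if cache else None
        if hit is not None:
            out.append(PmhcScore(peptide, allele, hit["affinity_nM"], hit["prime_rank"]))
            continue
        s = backend.pmhc(peptide, allele)
        if cache is not None:
            cache.put(key, {"affinity_nM": s.affinity_nM, "prime_rank": s.prime_rank})
        out.append(s)
    return out


def score_tcr(
    triples: Iterable[tuple[str, str, str]],
    backend: SurrogateBackend,
    cache: ScoreCache | None = None,
) -> list[TcrPmhcScore]:
    """Score (cdr3b, peptide, allele) triples; rank in [0,1] per triple."""
    out = []
    for cdr3b, peptide, allele in triples:
        validate_allele(allele)
        key = (peptide, allele, cdr3b, backend.name, backend.version)
        hit = cache.get(key) if cache else None
        if hit is not None:
            out.append(TcrPmhcScore(cdr3b, peptide, allele, hit["rank"]))
            continue
        s = backend.tcr(cdr3b, peptide, allele)
        if cache is not None:
            cache.put(key, {"rank": s.rank})
        out.append(s)
    return out
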