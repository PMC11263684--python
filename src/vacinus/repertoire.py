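"""Clonal expansion, migration and transition indices, and clone overlap.

Entropy-based repertoire statistics in the STARTRAC style, used to
characterize the T-cell response: how clonal a repertoire is (expansion),
how clones distribute across tissues (migration), how clones move between
phenotypic clusters (transition), and which expanded spleen clones reappear
in the tumor (overlap). All logarithms are natural; all indices live in
[0,1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def expansion_index(clone_sizes: Sequence[int]) -> float:
    """1 - H/H_max over clone-size frequencies.

    0 = all singletons (maximal entropy); 1 = a single expanded clone.
    Conventions for the degenerate one-clone repertoire: a single clone of
    size > 1 scores 1 (fully clonal), a single singleton scores 0.
    """
    sizes = np.asarray(list(clone_sizes), dtype=float)
    if sizes.size == 0:
        raise ValueError("empty clone-size list")
    if np.any(sizes <= 0):
        raise ValueError("clone sizes must be positive")
    if sizes.size == 1:
        return 1.0 if sizes[0] > 1 else 0.0
    return 1.0 - _entropy(sizes) / math.log(sizes.size)


def migration_index(
    clone_tissue_counts: Mapping[str, Mapping[str, int]],
    tissues: Sequence[str] | None = None,
) -> tuple[dict[str, float], float]:
    """Per-clone and size-weighted aggregate tissue-distribution entropy.

    Each clone scores H(tissue distribution)/ln(n_tissues); a clone confined
    to one tissue scores 0, an even split across all tissues scores 1. The
    aggregate is the clone-size-weighted mean.
    """
    if tissues is None:
        tissues = sorted({t for c in clone_tissue_counts.values() for t in c})
    if len(tissues) < 2:
        raise ValueError("migration index needs >=2 tissues")
    hmax = math.log(len(tissues))
    per_clone: dict[str, float] = {}
    weights: dict[str, float] = {}
    for clone, counts in clone_tissue_counts.items():
        vec = np.array([counts.get(t, 0) for t in tissues], dtype=float)
        total = vec.sum()
        if total == 0:
            continue
        per_clone[clone] = _entropy(vec) / hmax
        weights[clone] = total
    if not per_clone:
        return {}, 0.0
    w = np.array([weights[c] for c in per_clone])
    v = np.array([per_clone[c] for c in per_clone])
    return per_clone, float((w * v).sum() / w.sum())


def transition_index(
    clone_cluster_counts: Mapping[str, Mapping[str, int]],
    pair: tuple[str, str],
) -> float:
    """Size-weighted mean normalized two-state entropy over clones present
    in either cluster of the pair; symmetric in the pair. A pair sharing no
    clones is defined 0 (with a warning)."""
    a, b = pair
    num = 0.0
    den = 0.0
    for counts in clone_cluster_counts.values():
        na, nb = counts.get(a, 0), counts.get(b, 0)
        total = na + nb
        if total == 0:
            continue
        h = _entropy(np.array([na, nb], dtype=float)) / math.log(2)
        num += total * h
        den += total
    if den == 0:
        warnings.warn(f"no clones present in cluster pair {pair}")
        return 0.0
    return num / den


@dataclass
class CloneOverlap:
    """Expanded spleen clones re-found in the tumor by exact CDR3beta match."""

    overlapping: set[str]
    tumor_overlap_fraction: float
    spleen_overlap_fraction: float


def clone_overlap(
    spleen_sizes: Mapping[str, int],
    tumor_sizes: Mapping[str, int],
    min_spleen_size: int = 3,
) -> CloneOverlap:
    """Match spleen clones of size >= ``min_spleen_size`` to tumor clones by
    exact CDR3beta amino-acid identity.

    Returns the overlapping clone set and the fraction of tumor-infiltrating
    (and spleen) T cells belonging to overlapping clones. The default size
    filter keeps spleen clones of size > 2 only, reflecting the high clonal
    variability of the splenic repertoire.
    """
    eligible = {c for c, n in spleen_sizes.items() if n >= min_spleen_size}
    overlap = eligible & set(tumor_sizes)
    tumor_total = sum(tumor_sizes.values())
    spleen_total = sum(spleen_sizes.values())
    tumor_frac = (
        sum(tumor_sizes[c] for c in overlap) / tumor_total if tumor_total else 0.0
    )
    spleen_frac = (
        sum(spleen_sizes[c] for c in overlap) / spleen_total if spleen_total else 0.0
    )
    return CloneOverlap(overlap, tumor_frac, spleen_frac)


def clone_table_sizes(table: pd.DataFrame, key: str = "cdr3b_aa") -> dict[str, int]:
    """Collapse a clone table (one row per clone x stratum) to total sizes."""
    return table.groupby(key)["count"].sum().astype(int).to_dict()
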