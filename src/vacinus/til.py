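"""Putative tumor-reactive CD8+ TIL identification from single-cell data.

QC and CD8 gating of a cell x gene count matrix, Louvain clustering on the
kNN graph of PCA space, marker-based subtype annotation, the tumor-reactive
union (exhausted + proliferating + activated + effector), and extraction of
unique CDR3beta clonotypes from paired single-cell TCR data.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from scipy import sparse

# Marker panels for CD8+ T-cell subtypes (human TIL scheme).
HUMAN_SCHEME_MARKERS = {
    "proliferating": ["MKI67", "TOP2A"],
    "exhausted": ["PDCD1", "TIGIT", "HAVCR2", "LAG3", "CTLA4"],
    "effector": ["GZMA", "GZMK", "GZMH", "PRF1", "NKG7", "TNF", "GNLY", "IFNG"],
    "activated": ["HLA-DRA", "HLA-DRB1"],
    "naive/memory": ["SELL", "CCR7", "IL7R"],
    "nk_gd_like": ["TRGV9", "TRDV2", "KLRB1", "KLRC3"],
    "mait": ["TRAV1-2"],
}

# Mouse B16F10 melanoma scheme.
B16F10_SCHEME_MARKERS = {
    "activated": ["H2-AB1", "CD74", "CD69"],
    "exhausted": ["PDCD1", "TIGIT", "HAVCR2", "LAG3", "CTLA4"],
    "non_exhausted_memory_like": ["SELL", "CCR7", "IL7R", "TCF7"],
    "proliferative": ["MKI67", "TOP2A"],
    "nk_like": ["KLRB1C", "NCR1", "KLRK1"],
}

# Deterministic tie-break priority for subtype assignment.
TIE_PRIORITY = (
    "exhausted",
    "proliferating",
    "proliferative",
    "effector",
    "activated",
    "naive/memory",
    "non_exhausted_memory_like",
    "nk_gd_like",
    "nk_like",
    "mait",
)


@dataclass(frozen=True)
class SubtypeScheme:
    """Subtype -> marker genes, plus which subtypes count as tumor-reactive."""

    markers: dict[str, list[str]]
    reactive_union: frozenset[str]
    name: str = "custom"

    def __post_init__(self):
        if not self.reactive_union <= set(self.markers):
            raise ValueError("reactive_union contains unknown subtypes")
        for subtype, genes in self.markers.items():
            if not genes:
                raise ValueError(f"empty marker list for {subtype}")


HUMAN_SCHEME = SubtypeScheme(
    markers=HUMAN_SCHEME_MARKERS,
    reactive_union=frozenset({"proliferating", "exhausted", "effector", "activated"}),
    name="human",
)

B16F10_SCHEME = SubtypeScheme(
    markers=B16F10_SCHEME_MARKERS,
    reactive_union=frozenset({"exhausted", "proliferative", "activated"}),
    name="b16f10",
)


def get_scheme(name: str) -> SubtypeScheme:
    if name == "human":
        return HUMAN_SCHEME
    if name == "b16f10":
        return B16F10_SCHEME
    raise KeyError(f"unknown subtype scheme {name!r}")


@dataclass
class QcThresholds:
    min_genes: int = 200
    max_mito_fraction: float = 0.2
    cd8_genes: tuple[str, ...] = ("CD8A", "CD8B")
    cd4_gene: str = "CD4"
    cd8_min_count: int = 1  # CD8 expression > 0
    cd4_max_count: int = 0  # CD4 expression = 0


def qc_and_select_cd8(adata: AnnData, thresholds: QcThresholds | None = None) -> AnnData:
    """Drop low-quality cells, then keep CD8-expressing, CD4-negative cells.

    QC gates: detected genes >= min_genes and mitochondrial count fraction
    <= max_mito_fraction (genes prefixed MT-/mt-). The CD8/CD4 gate acts on
    raw counts: sum of CD8A/CD8B counts >= cd8_min_count and CD4 counts <=
    cd4_max_count. Gate-by-gate cell counts are logged in ``adata.uns``.
    """
    th = thresholds or QcThresholds()
    adata.var_names = adata.var_names.str.upper()
    if not set(th.cd8_genes) <= set(adata.var_names) or th.cd4_gene not in adata.var_names:
        raise KeyError("CD8A/CD8B/CD4 must be present in the gene panel")
    X = adata.X
    dense = X.toarray() if sparse.issparse(X) else np.asarray(X)
    log: dict[str, int] = {"input": adata.n_obs}

    n_genes = (dense > 0).sum(axis=1)
    keep = n_genes >= th.min_genes
    log["after_min_genes"] = int(keep.sum())

    mito = adata.var_names.str.startswith("MT-")
    if mito.any():
        totals = dense.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, dense[:, mito].sum(axis=1) / totals, 1.0)
        keep &= frac <= th.max_mito_fraction
    log["after_mito"] = int(keep.sum())

    cd8_idx = [adata.var_names.get_loc(g) for g in th.cd8_genes]
    cd4_idx = adata.var_names.get_loc(th.cd4_gene)
    cd8_counts = dense[:, cd8_idx].sum(axis=1)
    keep &= (cd8_counts >= th.cd8_min_count) & (dense[:, cd4_idx] <= th.cd4_max_count)
    log["after_cd8_cd4_gate"] = int(keep.sum())

    out = adata[keep].copy()
    out.uns["qc_log"] = log
    return out


def cluster_cells(
    adata: AnnData,
    n_pcs: int = 20,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Standard clustering: depth normalization, log1p, PCA, kNN graph,
    Louvain community detection (igraph multilevel). Deterministic for a
    fixed seed; labels are stored in ``adata.obs['cluster']`` and returned.
    """
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells to cluster")
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    n_pcs_eff = min(n_pcs, adata.n_obs - 1, adata.n_vars - 1)
    if n_pcs_eff < n_pcs:
        warnings.warn(f"reducing PCs from {n_pcs} to {n_pcs_eff}")
    sc.pp.pca(adata, n_comps=n_pcs_eff, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, adata.n_obs - 1),
                    n_pcs=n_pcs_eff, random_state=seed)

    conn = adata.obsp["connectivities"].tocoo()
    mask = conn.row < conn.col
    g = ig.Graph(
        n=adata.n_obs,
        edges=list(zip(conn.row[mask], conn.col[mask])),
        edge_attrs={"weight": conn.data[mask].tolist()},
    )
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    ig.set_random_number_generator(random)  # restore default RNG
    labels = pd.Series(part.membership, index=adata.obs_names, name="cluster").astype(str)
    adata.obs["cluster"] = labels.astype("category")
    return labels


def annotate_subtypes(
    adata: AnnData,
    labels: pd.Series,
    scheme: SubtypeScheme = HUMAN_SCHEME,
) -> dict[str, str]:
    """Assign each cluster the subtype with the highest mean marker score.

    The score of a subtype in a cluster is the mean over its marker genes of
    z-scored log-normalized expression, averaged over the cluster's cells.
    Ties break by a fixed priority order (exhausted > proliferating >
    effector > activated > others). Markers absent from the panel are
    scored over the present subset with a warning; a reactive subtype with
    no marker present raises.
    """
    adata.var_names = adata.var_names.str.upper()
    X = adata.X
    dense = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    mu = dense.mean(axis=0)
    sd = dense.std(axis=0)
    sd[sd == 0] = 1.0
    z = (dense - mu) / sd

    present: dict[str, list[int]] = {}
    for subtype, genes in scheme.markers.items():
        genes_up = [g.upper() for g in genes]
        idx = [adata.var_names.get_loc(g) for g in genes_up if g in adata.var_names]
        missing = [g for g in genes_up if g not in adata.var_names]
        if missing:
            warnings.warn(f"{subtype}: markers absent from panel: {missing}")
        if not idx:
            if subtype in scheme.reactive_union:
                raise KeyError(
                    f"no marker of reactive subtype {subtype!r} present in panel"
                )
            continue
        present[subtype] = idx

    priority = {s: i for i, s in enumerate(TIE_PRIORITY)}
    assignment: dict[str, str] = {}
    for cluster in sorted(labels.unique()):
        cells = (labels == cluster).to_numpy()
        scores = {
            subtype: float(z[np.ix_(cells, idx)].mean())
            for subtype, idx in present.items()
        }
        best = max(scores.values())
        tied = sorted(
            (s for s, v in scores.items() if np.isclose(v, best, atol=1e-12)),
            key=lambda s: priority.get(s, len(priority)),
        )
        assignment[str(cluster)] = tied[0]
    return assignment


def reactive_union(
    labels: pd.Series,
    assignment: dict[str, str],
    scheme: SubtypeScheme = HUMAN_SCHEME,
) -> tuple[pd.Index, float]:
    """Cells in clusters annotated as tumor-reactive subtypes, and their
    fraction of all CD8+ cells."""
    reactive_clusters = {
        c for c, s in assignment.items() if s in scheme.reactive_union
    }
    cells = labels.index[labels.astype(str).isin(reactive_clusters)]
    fraction = len(cells) / len(labels) if len(labels) else 0.0
    return cells, fraction


@dataclass
class Clonotype:
    clone_id: str
    cdr3b_aa: str
    v_gene: str | None = None
    j_gene: str | None = None
    cell_barcodes: frozenset[str] = field(default_factory=frozenset)
    tissue_counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.cell_barcodes)


def extract_clonotypes(
    cell_barcodes: pd.Index | list[str],
    tcr_table: pd.DataFrame,
    tissue_by_barcode: pd.Series | None = None,
) -> tuple[list[Clonotype], dict[str, int]]:
    """Unique CDR3beta clonotypes among the given cells.

    ``tcr_table`` is an AIRR-style rearrangement table with columns cell_id,
    junction_aa, v_call, j_call, productive, duplicate_count. Only productive
    beta chains are used; a barcode carrying conflicting beta chains keeps the
    highest-UMI chain. Cells without a beta chain are dropped and counted.
    """
    cells = set(map(str, cell_barcodes))
    t = tcr_table.copy()
    t["cell_id"] = t["cell_id"].astype(str)
    if "productive" in t.columns:
        t = t[t["productive"].astype(str).str.upper().isin({"T", "TRUE", "1"})]
    t = t[t["cell_id"].isin(cells) & t["junction_aa"].notna() & (t["junction_aa"] != "")]

    if "duplicate_count" in t.columns:
        t = t.sort_values("duplicate_count", ascending=False)
    n_before = t["cell_id"].nunique()
    t = t.drop_duplicates(subset="cell_id", keep="first")
    log = {
        "cells_in": len(cells),
        "cells_with_beta": n_before,
        "cells_without_beta": len(cells) - n_before,
        "conflicting_barcodes_resolved": n_before - t["cell_id"].nunique(),
    }

    clonotypes = []
    for i, (cdr3, grp) in enumerate(sorted(t.groupby("junction_aa"))):
        barcodes = frozenset(grp["cell_id"])
        tissue_counts: dict[str, int] = {}
        if tissue_by_barcode is not None:
            tissue_counts = (
                tissue_by_barcode.reindex(list(barcodes)).value_counts().to_dict()
            )
        clonotypes.append(
            Clonotype(
                clone_id=f"clone_{i:05d}",
                cdr3b_aa=cdr3,
                v_gene=grp["v_call"].iloc[0] if "v_call" in grp else None,
                j_gene=grp["j_call"].iloc[0] if "j_call" in grp else None,
                cell_barcodes=barcodes,
                tissue_counts=tissue_counts,
            )
        )
    return clonotypes, log
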