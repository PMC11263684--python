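"""Single-cell TIL pipeline: gating, clustering, annotation, clonotypes."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from sklearn.metrics import adjusted_rand_score

from vacinus.simulate import TilSpec, make_til_dataset
from vacinus.til import (
    HUMAN_SCHEME,
    QcThresholds,
    SubtypeScheme,
    annotate_subtypes,
    cluster_cells,
    extract_clonotypes,
    get_scheme,
    qc_and_select_cd8,
    reactive_union,
)

VACUOUS_QC = QcThresholds(min_genes=0, max_mito_fraction=1.0)


def test_cd8_cd4_gate_keeps_exactly_planted_cd8_cells():
    adata, _, truth = make_til_dataset(TilSpec(seed=2, n_cells=100, n_cd4_cells=50))
    out = qc_and_select_cd8(adata, VACUOUS_QC)
    assert out.n_obs == 100
    assert not any(b.startswith("cd4cell") for b in out.obs_names)


def test_zero_gene_cell_removed_at_qc():
    adata, _, _ = make_til_dataset(TilSpec(seed=2, n_cells=50))
    adata.X[0, :] = 0.0
    out = qc_and_select_cd8(adata, QcThresholds(min_genes=1, max_mito_fraction=1.0))
    assert adata.obs_names[0] not in out.obs_names
    assert out.uns["qc_log"]["after_min_genes"] == 49


def test_missing_gating_genes_error():
    adata = AnnData(
        X=np.ones((5, 3)), var=pd.DataFrame(index=["GZMA", "GZMB", "NKG7"])
    )
    with pytest.raises(KeyError, match="CD8A"):
        qc_and_select_cd8(adata, VACUOUS_QC)


def test_clustering_recovers_three_planted_programs(three_program_dataset):
    adata, _, truth = three_program_dataset
    qc = qc_and_select_cd8(adata.copy(), QcThresholds(min_genes=5))
    labels = cluster_cells(qc, seed=0, resolution=0.5)
    planted = truth.set_index("barcode").loc[labels.index, "subtype"]
    assert adjusted_rand_score(planted, labels) >= 0.9


def test_clustering_deterministic_for_fixed_seed(three_program_dataset):
    adata, _, _ = three_program_dataset
    l1 = cluster_cells(qc_and_select_cd8(adata.copy(), VACUOUS_QC), seed=4)
    l2 = cluster_cells(qc_and_select_cd8(adata.copy(), VACUOUS_QC), seed=4)
    assert (l1 == l2).all()


def test_single_program_low_resolution_gives_one_cluster():
    comp = {"effector": 1.0}
    adata, _, _ = make_til_dataset(TilSpec(seed=6, n_cells=80, composition=comp))
    labels = cluster_cells(adata, seed=0, resolution=0.05)
    assert labels.nunique() == 1


def test_annotation_assigns_planted_programs(three_program_dataset):
    adata, _, truth = three_program_dataset
    qc = qc_and_select_cd8(adata.copy(), QcThresholds(min_genes=5))
    labels = cluster_cells(qc, seed=0, resolution=0.5)
    assignment = annotate_subtypes(qc, labels, HUMAN_SCHEME)
    planted = truth.set_index("barcode").loc[labels.index, "subtype"]
    for cluster, subtype in assignment.items():
        majority = planted[labels == cluster].mode()[0]
        assert subtype == majority


def test_annotation_tie_breaks_by_priority():
    rng = np.random.default_rng(0)
    genes = sorted({g for gs in HUMAN_SCHEME.markers.values() for g in gs}) + [
        "CD8A",
        "CD8B",
        "CD4",
    ]
    X = np.ones((30, len(genes)))  # uniform expression: every score ties at 0
    adata = AnnData(X=X, var=pd.DataFrame(index=genes))
    adata.obs_names = [f"c{i}" for i in range(30)]
    labels = pd.Series(["0"] * 30, index=adata.obs_names)
    assignment = annotate_subtypes(adata, labels, HUMAN_SCHEME)
    assert assignment["0"] == "exhausted"  # first in the priority order


def test_annotation_subtype_score_invariant_to_gene_order_and_depth():
    adata, _, _ = make_til_dataset(TilSpec(seed=3, n_cells=60))
    labels = pd.Series(
        np.repeat(["0", "1"], 30)[: adata.n_obs], index=adata.obs_names
    )
    base = annotate_subtypes(adata.copy(), labels, HUMAN_SCHEME)
    perm = np.random.default_rng(1).permutation(adata.n_vars)
    shuffled = adata[:, perm].copy()
    assert annotate_subtypes(shuffled, labels, HUMAN_SCHEME) == base
    scaled = adata.copy()
    scaled.X = scaled.X * 3.0
    assert annotate_subtypes(scaled, labels, HUMAN_SCHEME) == base


def test_reactive_union_fraction_arithmetic():
    labels = pd.Series(
        ["ex"] * 40 + ["eff"] * 20 + ["naive"] * 40,
        index=[f"c{i}" for i in range(100)],
    )
    assignment = {"ex": "exhausted", "eff": "effector", "naive": "naive/memory"}
    cells, frac = reactive_union(labels, assignment, HUMAN_SCHEME)
    assert frac == pytest.approx(0.6)
    assert len(cells) == 60
    # no reactive clusters
    _, f0 = reactive_union(labels, {k: "naive/memory" for k in assignment}, HUMAN_SCHEME)
    assert f0 == 0.0
    # all reactive
    _, f1 = reactive_union(labels, {k: "exhausted" for k in assignment}, HUMAN_SCHEME)
    assert f1 == 1.0


def test_scheme_presets_and_validation():
    assert get_scheme("b16f10").reactive_union == {
        "exhausted",
        "proliferative",
        "activated",
    }
    with pytest.raises(ValueError):
        SubtypeScheme(markers={"a": ["G1"]}, reactive_union=frozenset({"b"}))


# ---------------------------------------------------------------------------
# clonotype extraction


def _airr(rows):
    return pd.DataFrame(
        rows, columns=["cell_id", "junction_aa", "v_call", "j_call", "productive", "duplicate_count"]
    )


def test_clonotype_partition_arithmetic():
    rows = [
        (f"c{i}", cdr3, "TRBV1", "TRBJ1", "T", 5)
        for i, cdr3 in enumerate(
            ["CASSAF", "CASSAF", "CASSBF", "CASSCF", "CASSCF", "CASSCF", "CASSDF"]
        )
    ]
    clones, log = extract_clonotypes([f"c{i}" for i in range(10)], _airr(rows))
    assert len(clones) == 4
    assert sum(c.size for c in clones) == 7 <= 10
    assert log["cells_without_beta"] == 3


def test_conflicting_chains_keep_highest_umi():
    rows = [("c0", "CASSAF", "TRBV1", "TRBJ1", "T", 2), ("c0", "CASSBF", "TRBV1", "TRBJ1", "T", 9)]
    clones, _ = extract_clonotypes(["c0"], _airr(rows))
    assert len(clones) == 1 and clones[0].cdr3b_aa == "CASSBF"


def test_nonproductive_chains_ignored():
    rows = [("c0", "CASSAF", "TRBV1", "TRBJ1", "F", 2)]
    clones, log = extract_clonotypes(["c0"], _airr(rows))
    assert clones == [] and log["cells_without_beta"] == 1


def test_planted_expanded_clone_recovered():
    adata, airr, truth = make_til_dataset(TilSpec(seed=8, n_cells=200))
    biggest = truth.groupby("cdr3b_aa").size().idxmax()
    expected = truth.groupby("cdr3b_aa").size().max()
    clones, _ = extract_clonotypes(truth["barcode"], airr)
    got = {c.cdr3b_aa: c.size for c in clones}
    assert got[biggest] == expected
    assert sum(got.values()) == len(truth)
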