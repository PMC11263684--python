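"""Synthetic data generators for every pipeline input.

Generates desk-scale stand-ins for cohort data: proteins with planted
somatic variants plus expression attributes, single-cell count matrices with
planted subtype expression programs and clonal structure, AIRR clonotype
tables, and labeled feature sets with a known generative logistic model.
Every generator is a pure function of its spec (seed mandatory) and emits
ground-truth tables sufficient to score downstream recovery tests.

Distribution choices are the conventional minimal models for these data
types: negative-binomial counts, log-normal TPM, beta VAF, heavy-tailed
(geometric) clone sizes. Defaults mirror the study conditions the pipeline
targets — e.g. a 57.6% tumor-reactive CD8 fraction with clonal expansion
concentrated in reactive subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .peptides import VariantClass, VariantRecord
from .til import HUMAN_SCHEME, SubtypeScheme

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Default subtype composition of the CD8+ TIL pool; the reactive subtypes
#: (exhausted + effector + activated + proliferating) sum to 0.576.
DEFAULT_COMPOSITION = {
    "exhausted": 0.22,
    "effector": 0.20,
    "activated": 0.10,
    "proliferating": 0.056,
    "naive/memory": 0.28,
    "nk_gd_like": 0.10,
    "mait": 0.044,
}


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def random_cdr3(rng: np.random.Generator, core_len: int = 8) -> str:
    return "CASS" + "".join(rng.choice(list(AA), size=core_len)) + "F"


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class VariantSetSpec:
    seed: int
    n_variants: int = 20
    class_mix: tuple[float, float, float] = (0.7, 0.1, 0.2)  # missense, inframe, fs
    protein_length: tuple[int, int] = (40, 120)
    tpm_lognormal: tuple[float, float] = (1.0, 1.2)  # mean, sigma of ln TPM
    vaf_beta: tuple[float, float] = (2.0, 4.0)
    reads_nb: tuple[float, float] = (30.0, 0.5)  # mean, dispersion


def make_variant_set(
    spec: VariantSetSpec,
) -> tuple[list[VariantRecord], dict[str, str], pd.DataFrame]:
    """Random proteins with planted variants.

    Returns (variants, wild-type protein FASTA dict, truth table). The truth
    table carries, per variant, the planted alteration coordinates and the
    brute-force expected window counts for lengths 9 and 10 (computed by a
    naive all-substrings scan, independent of the enumeration code).
    """
    rng = np.random.default_rng(spec.seed)
    min_len, max_len = spec.protein_length
    if min_len < 12:
        raise ValueError("proteins shorter than 12 cannot host 10-mer windows")
    variants, proteins, truth_rows = [], {}, []
    classes = [VariantClass.MISSENSE, VariantClass.INFRAME_INDEL, VariantClass.FRAMESHIFT]
    for i in range(spec.n_variants):
        vid = f"var{i:03d}"
        gene = f"GENE{i:03d}"
        length = int(rng.integers(min_len, max_len + 1))
        wt = random_protein(rng, length)
        vclass = classes[rng.choice(3, p=spec.class_mix)]
        pos = int(rng.integers(1, length + 1))
        if vclass is VariantClass.MISSENSE:
            old = wt[pos - 1]
            new = rng.choice([a for a in AA if a != old])
            mt = wt[: pos - 1] + new + wt[pos:]
            altered = {pos}
        elif vclass is VariantClass.INFRAME_INDEL:
            ins = random_protein(rng, int(rng.integers(1, 4)))
            mt = wt[: pos - 1] + ins + wt[pos - 1 :]
            altered = set(range(pos, pos + len(ins)))
        else:  # frameshift: novel tail from pos to a new stop
            tail = random_protein(rng, int(rng.integers(5, 20)))
            mt = wt[: pos - 1] + tail
            altered = set(range(pos, len(mt) + 1))
        tpm = float(rng.lognormal(*spec.tpm_lognormal))
        vaf = float(rng.beta(*spec.vaf_beta))
        mean, disp = spec.reads_nb
        reads = int(rng.negative_binomial(1 / disp, 1 / (1 + mean * disp)))
        variants.append(
            VariantRecord(vid, gene, vclass, pos, wt, mt, vaf, reads, tpm)
        )
        proteins[gene] = wt
        # independent naive scan: count full windows covering >=1 altered pos
        counts = {}
        for L in (9, 10):
            wins = {
                mt[s : s + L]
                for s in range(0, len(mt) - L + 1)
                if any(s + 1 <= p <= s + L for p in altered)
            }
            counts[L] = len(wins)
        truth_rows.append(
            {
                "variant_id": vid,
                "class": vclass.value,
                "protein_pos": pos,
                "altered_lo": min(altered),
                "altered_hi": max(altered),
                "n_windows_9": counts[9],
                "n_windows_10": counts[10],
            }
        )
    return variants, proteins, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# single-cell TIL fixtures


@dataclass(frozen=True)
class TilSpec:
    seed: int
    n_cells: int = 600
    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    scheme: SubtypeScheme = HUMAN_SCHEME
    marker_effect_sd: float = 5.0  # in baseline sd of log1p counts
    baseline_mean: float = 1.0
    nb_dispersion: float = 0.1  # var = mu + disp * mu^2 (UMI-like)
    n_filler_genes: int = 40
    n_cd4_cells: int = 0  # planted CD4+ contaminants (removed by gating)
    spleen_fraction: float = 0.0
    expanded_clone_mean: float = 8.0  # geometric mean clone size, reactive
    nonreactive_clone_mean: float = 1.2


def _nb_draw(rng, mean: float, disp: float, size) -> np.ndarray:
    if disp <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / disp
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def make_til_dataset(
    spec: TilSpec,
) -> tuple[AnnData, pd.DataFrame, pd.DataFrame]:
    """Single-cell counts with planted subtype programs and clonal structure.

    Returns (AnnData, AIRR rearrangement table, truth table with per-cell
    subtype/clone/tissue). Counts are negative-binomial; each subtype's own
    marker genes are up-shifted by ``marker_effect_sd`` baseline standard
    deviations. Clones are drawn within subtypes, heavy-tailed in reactive
    subtypes and near-singleton elsewhere. CD8A/CD8B are expressed in every
    T cell; ``n_cd4_cells`` adds CD4+ contaminants for gating tests.
    """
    comp = spec.composition
    if abs(sum(comp.values()) - 1.0) > 1e-8:
        raise ValueError("composition fractions must sum to 1")
    unknown = set(comp) - set(spec.scheme.markers)
    if unknown:
        raise ValueError(f"composition names unknown subtypes: {unknown}")
    rng = np.random.default_rng(spec.seed)

    subtypes = sorted(comp)
    n_per = {s: int(round(comp[s] * spec.n_cells)) for s in subtypes}
    drift = spec.n_cells - sum(n_per.values())
    n_per[subtypes[0]] += drift

    marker_genes = sorted(
        {g.upper() for genes in spec.scheme.markers.values() for g in genes}
    )
    genes = (
        marker_genes
        + ["CD8A", "CD8B", "CD4"]
        + [f"FILLER{i:03d}" for i in range(spec.n_filler_genes)]
    )
    gidx = {g: i for i, g in enumerate(genes)}

    # marker up-shift measured in baseline standard deviations of log1p
    # counts (the space clustering operates in); delta-method sd.
    mu0, disp = spec.baseline_mean, spec.nb_dispersion
    sd_log = np.sqrt(mu0 + disp * mu0**2) / (1.0 + mu0)
    mu_hi = float(np.expm1(np.log1p(mu0) + spec.marker_effect_sd * sd_log))

    rows, subtype_of, barcodes = [], [], []
    for s in subtypes:
        for _ in range(n_per[s]):
            subtype_of.append(s)
    rng.shuffle(subtype_of)
    X = _nb_draw(rng, mu0, disp, size=(spec.n_cells, len(genes))).astype(float)
    for i, s in enumerate(subtype_of):
        own = [gidx[g.upper()] for g in spec.scheme.markers[s] if g.upper() in gidx]
        X[i, own] = _nb_draw(rng, mu_hi, disp, size=len(own))
        barcodes.append(f"cell{i:05d}")
    X[:, gidx["CD8A"]] = rng.poisson(4.0, size=spec.n_cells) + 1
    X[:, gidx["CD8B"]] = rng.poisson(3.0, size=spec.n_cells) + 1
    X[:, gidx["CD4"]] = 0

    # planted CD4+ contaminants (fail the CD8/CD4 gate)
    if spec.n_cd4_cells:
        Xc = _nb_draw(rng, mu0, disp, size=(spec.n_cd4_cells, len(genes))).astype(float)
        Xc[:, gidx["CD4"]] = rng.poisson(4.0, size=spec.n_cd4_cells) + 1
        Xc[:, gidx["CD8A"]] = 0
        Xc[:, gidx["CD8B"]] = 0
        X = np.vstack([X, Xc])
        barcodes += [f"cd4cell{i:05d}" for i in range(spec.n_cd4_cells)]
        subtype_of += ["cd4_contaminant"] * spec.n_cd4_cells

    tissue = np.where(
        rng.random(len(barcodes)) < spec.spleen_fraction, "spleen", "tumor"
    )

    # clonal structure within subtypes
    reactive = spec.scheme.reactive_union
    clone_of: list[str] = [""] * len(barcodes)
    cdr3_of: dict[str, str] = {}
    clone_counter = 0
    for s in set(subtype_of):
        idx = [i for i, t in enumerate(subtype_of) if t == s]
        rng.shuffle(idx)
        mean_size = (
            spec.expanded_clone_mean if s in reactive else spec.nonreactive_clone_mean
        )
        k = 0
        while k < len(idx):
            size = int(min(rng.geometric(1.0 / mean_size), len(idx) - k))
            cid = f"clone{clone_counter:05d}"
            cdr3_of[cid] = random_cdr3(rng)
            clone_counter += 1
            for j in idx[k : k + size]:
                clone_of[j] = cid
            k += size

    adata = AnnData(
        X=X,
        obs=pd.DataFrame({"tissue": tissue}, index=barcodes),
        var=pd.DataFrame(index=genes),
    )
    airr = pd.DataFrame(
        {
            "cell_id": barcodes,
            "junction_aa": [cdr3_of[c] for c in clone_of],
            "v_call": "TRBV19",
            "j_call": "TRBJ2-7",
            "productive": "T",
            "duplicate_count": rng.integers(1, 20, size=len(barcodes)),
        }
    )
    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "subtype": subtype_of,
            "clone_id": clone_of,
            "cdr3b_aa": [cdr3_of[c] for c in clone_of],
            "tissue": tissue,
            "reactive": [s in reactive for s in subtype_of],
        }
    )
    return adata, airr, truth


# ---------------------------------------------------------------------------
# labeled feature sets


@dataclass(frozen=True)
class LabeledFeatureSpec:
    seed: int
    n: int = 400
    n_noise: int = 8
    informative: dict[str, float] = field(
        default_factory=lambda: {"signal_a": 2.0, "signal_b": -2.0}
    )
    intercept: float = -1.0
    n_patients: int = 20


def make_labeled_features(
    spec: LabeledFeatureSpec,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, dict[str, float]]:
    """Standard-normal features with a planted logistic label model.

    Returns (X, y, groups, coefficients). The informative features carry the
    stated coefficients; noise features have zero effect. Groups emulate
    patients for grouped cross-validation.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.informative) + [f"noise_{i}" for i in range(spec.n_noise)]
    X = pd.DataFrame(
        rng.standard_normal((spec.n, len(names))), columns=names
    )
    eta = spec.intercept + sum(
        coef * X[name].to_numpy() for name, coef in spec.informative.items()
    )
    y = (rng.random(spec.n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    groups = np.arange(spec.n) % spec.n_patients
    coefs = {"intercept": spec.intercept, **spec.informative}
    return X, y, groups, coefs
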