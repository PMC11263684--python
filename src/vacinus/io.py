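"""Readers and writers for the pipeline's file formats.

Variants come in as a flat TSV or a VCF 4.x with a protein-consequence INFO
tag; proteins as FASTA; single-cell counts as an MTX directory (CellRanger
layout) or dense TSV; TCR data as AIRR Rearrangement TSV. Outputs are TSV
tables plus JSON logs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from anndata import AnnData
from Bio import SeqIO

from .peptides import CandidatePeptide, VariantClass, VariantRecord

VARIANT_TSV_COLUMNS = [
    "variant_id",
    "gene",
    "class",
    "protein_pos",
    "wt_protein_id",
    "mt_protein_seq",
    "vaf",
    "read_count",
    "tpm",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(proteins: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in proteins.items():
            fh.write(f">{name}\n{seq}\n")


def read_variants_tsv(path: str | Path, proteins: dict[str, str]) -> list[VariantRecord]:
    """Flat-TSV variant input; wild-type sequences are resolved from the
    protein FASTA by ``wt_protein_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(VARIANT_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        if row.wt_protein_id not in proteins:
            raise KeyError(f"{row.variant_id}: protein {row.wt_protein_id} not in FASTA")
        out.append(
            VariantRecord(
                variant_id=row.variant_id,
                gene=row.gene,
                variant_class=VariantClass(row[2]),
                protein_pos=int(row.protein_pos),
                wt_protein=proteins[row.wt_protein_id],
                mt_protein=row.mt_protein_seq,
                vaf=float(row.vaf),
                read_count=int(row.read_count),
                tpm=float(row.tpm),
            )
        )
    return out


def read_variants_vcf(
    path: str | Path,
    proteins: dict[str, str],
    info_tag: str = "PCSQ",
) -> list[VariantRecord]:
    """VCF input: each record carries a protein-consequence annotation in
    INFO[``info_tag``] as gene|class|protein_pos|wt_protein_id|mt_protein_seq,
    plus VAF, RC (read count) and TPM INFO fields."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if info_tag not in rec.info:
                continue
            raw = rec.info[info_tag]
            csq = raw[0] if isinstance(raw, tuple) else raw
            gene, vclass, pos, prot_id, mt_seq = csq.split("|")
            if prot_id not in proteins:
                raise KeyError(f"{rec.id}: protein {prot_id} not in FASTA")
            out.append(
                VariantRecord(
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    gene=gene,
                    variant_class=VariantClass(vclass),
                    protein_pos=int(pos),
                    wt_protein=proteins[prot_id],
                    mt_protein=mt_seq,
                    vaf=float(rec.info["VAF"]),
                    read_count=int(rec.info["RC"]),
                    tpm=float(rec.info["TPM"]),
                )
            )
    return out


def write_candidates_tsv(candidates: Sequence[CandidatePeptide], path: str | Path) -> None:
    rows = [
        {
            "peptide_id": c.peptide_id,
            "mt_seq": c.mt_seq,
            "wt_seq": c.wt_seq or "",
            "mut_positions": ",".join(map(str, sorted(c.mut_positions))),
            "source_variant": c.source_variant,
            "gene": c.gene,
            "allele": c.allele or "",
            "vaf": c.vaf,
            "read_count": c.read_count,
            "tpm": c.tpm,
            "affinity_nM": "" if c.affinity_nM is None else c.affinity_nM,
            "prime_rank": "" if c.prime_rank is None else c.prime_rank,
        }
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | Path) -> list[CandidatePeptide]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CandidatePeptide(
                peptide_id=row.peptide_id,
                mt_seq=row.mt_seq,
                wt_seq=row.wt_seq or None,
                mut_positions=frozenset(
                    int(x) for x in row.mut_positions.split(",") if x
                ),
                source_variant=row.source_variant,
                gene=row.gene,
                allele=row.allele or None,
                vaf=float(row.vaf),
                read_count=int(float(row.read_count)),
                tpm=float(row.tpm),
                affinity_nM=float(row.affinity_nM) if row.affinity_nM else None,
                prime_rank=float(row.prime_rank) if row.prime_rank else None,
            )
        )
    return out


def read_counts_mtx(mtx_dir: str | Path) -> AnnData:
    """CellRanger-layout directory: matrix.mtx (genes x cells), barcodes.tsv,
    features.tsv (or genes.tsv)."""
    from scipy.io import mmread

    d = Path(mtx_dir)
    mat = mmread(str(d / "matrix.mtx")).tocsr().T  # cells x genes
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    feat_path = d / "features.tsv"
    if not feat_path.exists():
        feat_path = d / "genes.tsv"
    feats = pd.read_csv(feat_path, sep="\t", header=None)
    gene_col = 1 if feats.shape[1] > 1 else 0
    return AnnData(
        X=mat,
        obs=pd.DataFrame(index=barcodes.to_list()),
        var=pd.DataFrame(index=feats[gene_col].astype(str).to_list()),
    )


def write_counts_mtx(adata: AnnData, mtx_dir: str | Path) -> None:
    from scipy import sparse
    from scipy.io import mmwrite

    d = Path(mtx_dir)
    d.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    mmwrite(str(d / "matrix.mtx"), X.T.astype(int))
    pd.Series(adata.obs_names).to_csv(d / "barcodes.tsv", index=False, header=False)
    pd.DataFrame({"id": adata.var_names, "name": adata.var_names}).to_csv(
        d / "features.tsv", sep="\t", index=False, header=False
    )


def read_airr_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns or "junction_aa" not in df.columns:
        raise ValueError("AIRR table needs cell_id and junction_aa columns")
    if "duplicate_count" in df.columns:
        df["duplicate_count"] = pd.to_numeric(df["duplicate_count"], errors="coerce")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str))
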