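"""Readers and writers for the pipeline's file contracts.

VCF v4.2 with CHROM = transcript ID and POS = 1-based offset within the
transcript; GT is the only required FORMAT field (DP optional). Reading goes
through cyvcf2; writing is a plain-text emitter since the files are GT-only.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeTable

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_CYVCF2_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def write_vcf(
    table: GenotypeTable,
    path,
    positions: Optional[np.ndarray] = None,
    contig_lengths: Optional[dict] = None,
) -> None:
    """Write a GT-only (plus DP when present) VCF v4.2.

    ``positions`` defaults to the 1-based rank of each SNP within its
    transcript, taken in table order.
    """
    path = Path(path)
    if positions is None:
        seen: dict = {}
        positions = np.empty(table.n_snps, dtype=int)
        for i, tid in enumerate(table.transcript_ids):
            seen[tid] = seen.get(tid, 0) + 1
            positions[i] = seen[tid]
    has_dp = table.depth is not None
    fmt = "GT:DP" if has_dp else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for tid in dict.fromkeys(table.transcript_ids):
            length = (contig_lengths or {}).get(tid)
            if length is not None:
                fh.write(f"##contig=<ID={tid},length={int(length)}>\n")
            else:
                fh.write(f"##contig=<ID={tid}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.individuals)
            + "\n"
        )
        for i in range(table.n_snps):
            qual = table.qual[i]
            qual_str = "." if np.isnan(qual) else f"{qual:g}"
            fields = [
                str(table.transcript_ids[i]),
                str(int(positions[i])),
                str(table.snp_ids[i]),
                "A",
                "G",
                qual_str,
                "PASS",
                ".",
                fmt,
            ]
            for j in range(table.n_individuals):
                gt = _GT_STRINGS[int(table.genotypes[i, j])]
                if has_dp:
                    gt = f"{gt}:{int(table.depth[i, j])}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> GenotypeTable:
    """Parse a VCF into a GenotypeTable (GT, QUAL, DP when available).

    Multi-allelic records are kept here and removed by the biallelic step of
    the SNP filter; SNP IDs default to CHROM:POS when the ID column is empty.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    genotypes, snp_ids, transcript_ids, quals, depths = [], [], [], [], []
    multiallelic = []
    any_dp = False
    for var in vcf:
        n_alt = len(var.ALT)
        multiallelic.append(n_alt != 1)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        transcript_ids.append(var.CHROM)
        quals.append(np.nan if var.QUAL is None else float(var.QUAL))
        gt = _CYVCF2_DOSAGE[np.asarray(var.gt_types, dtype=int)]
        genotypes.append(gt)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_dp = True
            dp = np.asarray(dp, dtype=float).reshape(-1)
            dp[dp < 0] = np.nan
        depths.append(dp)
    vcf.close()
    if not genotypes:
        raise ValueError(f"no variant records in {path}")
    n_ind = len(individuals)
    depth = None
    if any_dp:
        depth = np.vstack(
            [d if d is not None else np.full(n_ind, np.nan) for d in depths]
        )
    else:
        warnings.warn("VCF has no DP field; depth-based filtering will be skipped")
    genotypes = np.vstack(genotypes)
    # genotypes at multi-allelic sites are not interpretable as alt dosage
    multi = np.asarray(multiallelic)
    genotypes[multi] = MISSING
    table = GenotypeTable(
        genotypes=genotypes,
        snp_ids=np.asarray(snp_ids, dtype=object),
        transcript_ids=np.asarray(transcript_ids, dtype=object),
        individuals=individuals,
        qual=np.asarray(quals, dtype=float),
        depth=depth,
    )
    table.biallelic = ~multi  # type: ignore[attr-defined]
    return table


def read_matrix_tsv(path) -> pd.DataFrame:
    """transcripts x individuals matrix; first column = transcript IDs."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "transcript") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_hits_tsv(path) -> pd.DataFrame:
    """BLAST outfmt-6 style homology hits (named-column subset)."""
    df = pd.read_csv(path, sep="\t")
    required = {"qseqid", "sseqid", "pident", "length", "evalue", "qlen", "slen"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hits table missing columns: {sorted(missing)}")
    return df


def read_go_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"transcript", "go_id"}.issubset(df.columns):
        raise ValueError("GO annotation table needs columns: transcript, go_id")
    return df


def read_go_dag_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"child", "parent", "namespace"}.issubset(df.columns):
        raise ValueError("GO DAG edge list needs columns: child, parent, namespace")
    return df


def read_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"population", "lat", "lon"}.issubset(df.columns):
        raise ValueError("coordinates table needs columns: population, lat, lon")
    return df
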