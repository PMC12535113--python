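"""Core in-memory containers shared across the pipeline.

Genotypes are stored as alt-allele dosage (0/1/2) with -1 for missing calls;
expression as transcripts x individuals DataFrames (FPKM and raw counts with
identical row/column ordering). The population map ties individuals to
populations and populations to groups (the north/south contrast).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class PopMap:
    """individual -> population -> group assignment."""

    table: pd.DataFrame  # columns: individual, population, group

    def __post_init__(self) -> None:
        required = {"individual", "population", "group"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"popmap needs columns {sorted(required)}")
        if self.table["individual"].duplicated().any():
            raise ValueError("individuals must be unique in the popmap")

    @property
    def individuals(self) -> list[str]:
        return list(self.table["individual"])

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["group"]))

    def members(self, unit: str, level: str = "population") -> list[str]:
        col = "population" if level == "population" else "group"
        return list(self.table.loc[self.table[col] == unit, "individual"])

    def units(self, level: str) -> list[str]:
        return self.populations if level == "population" else self.groups

    def group_of(self, population: str) -> str:
        rows = self.table.loc[self.table["population"] == population, "group"]
        if rows.empty:
            raise KeyError(population)
        return rows.iloc[0]

    @classmethod
    def read_tsv(cls, path) -> "PopMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeTable:
    """Biallelic diploid genotypes, each SNP tagged with its host transcript.

    genotypes: (n_snps, n_individuals) int8 array of alt-allele dosage,
    MISSING (-1) for no-calls. ``depth`` is per-SNP x individual read depth
    or None when the source VCF carried no DP field.
    """

    genotypes: np.ndarray
    snp_ids: np.ndarray
    transcript_ids: np.ndarray
    individuals: list[str]
    qual: np.ndarray
    depth: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.transcript_ids = np.asarray(self.transcript_ids, dtype=object)
        self.qual = np.asarray(self.qual, dtype=float)
        n_snps, n_ind = self.genotypes.shape
        if not (len(self.snp_ids) == len(self.transcript_ids) == len(self.qual) == n_snps):
            raise ValueError("per-SNP arrays must match the genotype matrix")
        if len(self.individuals) != n_ind:
            raise ValueError("individual list must match the genotype matrix")

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeTable":
        return replace(
            self,
            genotypes=self.genotypes[mask],
            snp_ids=self.snp_ids[mask],
            transcript_ids=self.transcript_ids[mask],
            qual=self.qual[mask],
            depth=None if self.depth is None else self.depth[mask],
        )

    def columns_for(self, individuals: list[str]) -> np.ndarray:
        index = {ind: j for j, ind in enumerate(self.individuals)}
        return np.array([index[i] for i in individuals], dtype=int)

    def dosage_matrix(self) -> np.ndarray:
        """individuals x SNPs float matrix with NaN for missing calls."""
        d = self.genotypes.T.astype(float)
        d[d == MISSING] = np.nan
        return d


@dataclass
class ExpressionTable:
    """transcripts x individuals FPKM matrix with a parallel raw-count matrix."""

    fpkm: pd.DataFrame
    counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.counts is not None:
            if not self.fpkm.index.equals(self.counts.index) or not self.fpkm.columns.equals(
                self.counts.columns
            ):
                raise ValueError("FPKM and count matrices must share row/column ordering")

    @property
    def transcripts(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.fpkm.columns)

    def subset_transcripts(self, transcripts) -> "ExpressionTable":
        keep = [t for t in self.transcripts if t in set(transcripts)]
        return ExpressionTable(
            fpkm=self.fpkm.loc[keep],
            counts=None if self.counts is None else self.counts.loc[keep],
        )


@dataclass
class PairwiseMatrix:
    """Symmetric matrix over population (or group) labels.

    ``kind`` records the diagonal convention: distances and F_ST have a zero
    diagonal, similarities a unit diagonal.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "distance"  # distance | similarity

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "distance") -> "PairwiseMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


@dataclass
class TestResult:
    """Generic statistic container for the pipeline's hypothesis tests."""

    name: str
    estimate: float
    statistic: Optional[float] = None
    pvalue: Optional[float] = None
    n: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "n": self.n,
            **{f"meta_{k}": v for k, v in self.metadata.items()},
        }


@dataclass
class PCAResult:
    """Individual coordinates plus explained-variance fractions."""

    coordinates: pd.DataFrame  # individuals x PCs
    explained_variance_ratio: np.ndarray
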