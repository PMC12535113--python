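"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a two-group (north/south), four-population sampling
design: Balding-Nichols allele-frequency divergence between groups,
negative-binomial read counts with planted group-specific differential
expression, a planted candidate-gene-transcript (CGT) subset enriched among
the differentially expressed transcripts, homology hits that exercise the
CGT filter, a small three-namespace GO DAG, and population coordinates on a
latitudinal line. One global seed determines every output byte; each
component draws from its own fixed substream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ExpressionTable, GenotypeTable, PopMap
from . import io

_STREAM_TRUTH = 0
_STREAM_GENO = 1
_STREAM_EXPR = 2
_STREAM_ANNOT = 3


@dataclass
class SimConfig:
    """Study-design and effect-size knobs for the generator.

    Defaults describe a desk-scale version of a four-population latitudinal
    sampling design: two groups of two populations, a dozen individuals per
    population, strong between-group divergence (fst_target 0.5), two-log2
    group effects on a fifth of transcripts, and planted candidate-gene
    transcripts four-fold enriched among the differentially expressed set.
    """

    n_pops: int = 4
    pops_per_group: dict = field(
        default_factory=lambda: {"north": ["N1", "N2"], "south": ["S1", "S2"]}
    )
    n_per_pop: int = 12
    n_transcripts: int = 2000
    snps_per_transcript: float = 8.0  # Poisson mean
    fst_target: float = 0.5
    frac_cgt: float = 0.15
    frac_de: float = 0.2
    frac_divergent: float = 1.0  # fraction of transcripts whose SNPs diverge
    lfc_scale: float = 2.0  # |log2 fold change| of planted group effects
    nb_dispersion: float = 0.05
    cgt_de_enrichment: float = 4.0  # odds multiplier for CGTs being DE
    de_sign: Optional[int] = None  # None: random +/-1; +1: all south-up
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_cgt", "frac_de", "frac_divergent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.fst_target < 1.0:
            raise ValueError("fst_target must be in [0, 1)")
        if self.lfc_scale <= 0 or self.nb_dispersion <= 0:
            raise ValueError("lfc_scale and nb_dispersion must be positive")
        if self.cgt_de_enrichment < 1.0:
            raise ValueError("cgt_de_enrichment must be >= 1")
        pops = [p for ps in self.pops_per_group.values() for p in ps]
        if len(pops) != len(set(pops)):
            raise ValueError("groups must partition populations")
        if len(pops) != self.n_pops:
            raise ValueError("pops_per_group inconsistent with n_pops")
        if self.de_sign not in (None, 1, -1):
            raise ValueError("de_sign must be None, +1 or -1")

    def rng(self, stream: int) -> np.random.Generator:
        # fixed substream offsets under one global seed
        return np.random.default_rng([int(self.seed), int(stream)])

    @property
    def populations(self) -> list[str]:
        return [p for ps in self.pops_per_group.values() for p in ps]

    @property
    def groups(self) -> list[str]:
        return list(self.pops_per_group)


@dataclass
class SimTruth:
    """Ground truth planted by the generator (for power/recall measurement)."""

    transcript_ids: list[str]
    lengths: pd.Series  # bp per transcript
    cgt_transcripts: set
    de_transcripts: dict  # transcript -> +1 (south-up) or -1 (north-up)
    divergent_transcripts: set
    ancestral_freq: np.ndarray = None  # per SNP
    group_freq: pd.DataFrame = None  # SNP x group drawn frequencies
    snp_transcripts: np.ndarray = None

    def __post_init__(self) -> None:
        ids = set(self.transcript_ids)
        if not set(self.cgt_transcripts) <= ids or not set(self.de_transcripts) <= ids:
            raise ValueError("truth sets must be subsets of simulated transcripts")


def build_popmap(cfg: SimConfig) -> PopMap:
    rows = []
    for group, pops in cfg.pops_per_group.items():
        for pop in pops:
            for k in range(cfg.n_per_pop):
                rows.append({"individual": f"{pop}_{k:02d}", "population": pop, "group": group})
    return PopMap(pd.DataFrame(rows))


def _plant_truth(cfg: SimConfig) -> SimTruth:
    rng = cfg.rng(_STREAM_TRUTH)
    n = cfg.n_transcripts
    ids = [f"TR{i:05d}" for i in range(n)]
    lengths = pd.Series(
        np.clip(rng.lognormal(math.log(2000.0), 0.45, size=n), 300, 12000).astype(int),
        index=ids,
        name="length",
    )
    n_cgt = int(round(cfg.frac_cgt * n))
    cgt = set(rng.choice(ids, size=n_cgt, replace=False)) if n_cgt else set()
    # weighted sampling without replacement (Gumbel top-k): CGTs get odds
    # multiplier cgt_de_enrichment of being planted DE
    n_de = int(round(cfg.frac_de * n))
    de: dict = {}
    if n_de:
        logw = np.array(
            [math.log(cfg.cgt_de_enrichment) if t in cgt else 0.0 for t in ids]
        )
        keys = logw + rng.gumbel(size=n)
        chosen = np.argsort(-keys, kind="stable")[:n_de]
        for idx in sorted(chosen):
            sign = cfg.de_sign if cfg.de_sign is not None else int(rng.choice([-1, 1]))
            de[ids[idx]] = sign
    n_div = int(round(cfg.frac_divergent * n))
    divergent = set(rng.choice(ids, size=n_div, replace=False)) if n_div else set()
    return SimTruth(
        transcript_ids=ids,
        lengths=lengths,
        cgt_transcripts=cgt,
        de_transcripts=de,
        divergent_transcripts=divergent,
    )


def simulate_genotypes(cfg: SimConfig, truth: Optional[SimTruth] = None):
    """Draw SNP genotypes under a group-level Balding-Nichols model.

    Per SNP: ancestral frequency p ~ U(0.05, 0.95); each group draws its
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with F = fst_target
    (F = 0 or a non-divergent transcript: the group keeps the ancestral
    frequency); populations within a group share the group frequency;
    diploid genotypes are binomial draws. Returns (GenotypeTable, SimTruth).
    """
    if truth is None:
        truth = _plant_truth(cfg)
    rng = cfg.rng(_STREAM_GENO)
    popmap = build_popmap(cfg)
    n_per_tr = rng.poisson(cfg.snps_per_transcript, size=cfg.n_transcripts)
    snp_transcripts = np.repeat(np.asarray(truth.transcript_ids, dtype=object), n_per_tr)
    n_snps = len(snp_transcripts)
    snp_ids = np.array(
        [f"{tid}:snp{k}" for tid, cnt in zip(truth.transcript_ids, n_per_tr) for k in range(cnt)],
        dtype=object,
    )
    p_anc = rng.uniform(0.05, 0.95, size=n_snps)
    divergent_snp = np.array([t in truth.divergent_transcripts for t in snp_transcripts])
    F = cfg.fst_target
    group_freq = {}
    for group in cfg.groups:
        if F > 0:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            drawn = rng.beta(a, b)
        else:
            drawn = p_anc.copy()
        freq = np.where(divergent_snp, drawn, p_anc)
        group_freq[group] = freq
    individuals = popmap.individuals
    genotypes = np.empty((n_snps, len(individuals)), dtype=np.int8)
    for j, ind in enumerate(individuals):
        pop = popmap.table.loc[popmap.table["individual"] == ind, "population"].iloc[0]
        grp = popmap.group_of(pop)
        genotypes[:, j] = rng.binomial(2, group_freq[grp])
    qual = rng.uniform(30.0, 100.0, size=n_snps).round(1)
    table = GenotypeTable(
        genotypes=genotypes,
        snp_ids=snp_ids,
        transcript_ids=snp_transcripts,
        individuals=individuals,
        qual=qual,
    )
    truth.ancestral_freq = p_anc
    truth.group_freq = pd.DataFrame(group_freq)
    truth.snp_transcripts = snp_transcripts
    return table, truth


def simulate_expression(cfg: SimConfig, truth: SimTruth) -> ExpressionTable:
    """Negative-binomial counts with planted group effects, plus FPKM.

    Baseline means are log-normal; planted DE transcripts get a +/-lfc_scale
    log2 shift in the south group; per-individual library-size factors are
    log-normal (redrawn if below a tenth of the median factor); FPKM is
    computed from the counts, the simulated transcript lengths and the
    per-individual totals, so the two matrices are mutually consistent.
    """
    rng = cfg.rng(_STREAM_EXPR)
    popmap = build_popmap(cfg)
    individuals = popmap.individuals
    n = cfg.n_transcripts
    base = rng.lognormal(math.log(150.0), 1.2, size=n)
    factors = rng.lognormal(0.0, 0.15, size=len(individuals))
    while True:
        low = factors < 0.1 * np.median(factors)
        if not low.any():
            break
        factors[low] = rng.lognormal(0.0, 0.15, size=int(low.sum()))
    lfc = np.zeros(n)
    for i, tid in enumerate(truth.transcript_ids):
        if tid in truth.de_transcripts:
            lfc[i] = truth.de_transcripts[tid] * cfg.lfc_scale
    is_south = np.array(
        [popmap.group_of(popmap.table.iloc[j]["population"]) == "south"
         for j in range(len(individuals))]
    )
    mu = base[:, None] * np.power(2.0, lfc[:, None] * is_south[None, :]) * factors[None, :]
    r = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=truth.transcript_ids, columns=individuals)
    totals = counts_df.sum(axis=0).to_numpy(dtype=float)
    lengths = truth.lengths.loc[counts_df.index].to_numpy(dtype=float)
    fpkm = counts / (lengths[:, None] / 1e3) / (totals[None, :] / 1e6)
    fpkm_df = pd.DataFrame(fpkm, index=truth.transcript_ids, columns=individuals)
    return ExpressionTable(fpkm=fpkm_df, counts=counts_df)


def _toy_go_dag() -> pd.DataFrame:
    """Fixed ~60-term DAG: three namespaces, depth <= 5, a few diamonds."""
    edges = []

    def tree(ns_code: str, namespace: str, branching: list[int]) -> list[str]:
        level = [f"GO:{ns_code}00000"]
        counter = 1
        leaves = []
        for depth, width in enumerate(branching, start=1):
            nxt = []
            for parent in level:
                for _ in range(width):
                    term = f"GO:{ns_code}{counter:05d}"
                    counter += 1
                    edges.append({"child": term, "parent": parent, "namespace": namespace})
                    nxt.append(term)
            level = nxt
        leaves.extend(level)
        return leaves

    bp_leaves = tree("1", "BP", [3, 2, 2])  # 1+3+6+12 = 22 terms
    mf_leaves = tree("2", "MF", [3, 2])  # 1+3+6 = 10 terms
    cc_leaves = tree("3", "CC", [2, 2, 2])  # 1+2+4+8 = 15 terms
    # diamonds: give some deep terms a second, shallower parent
    edges.append({"child": "GO:100010", "parent": "GO:100002", "namespace": "BP"})
    edges.append({"child": "GO:200008", "parent": "GO:200001", "namespace": "MF"})
    edges.append({"child": "GO:300010", "parent": "GO:300001", "namespace": "CC"})
    df = pd.DataFrame(edges)
    df.attrs["leaves"] = bp_leaves + mf_leaves + cc_leaves
    return df


def simulate_annotations(cfg: SimConfig, truth: SimTruth):
    """Homology hits, GO annotations, toy GO DAG and population coordinates.

    Every planted CGT gets a hit passing all three homology criteria
    (e-value < 1e-3, identity > 50, alignment/subject length > 0.5); other
    transcripts get either no hit or a hit failing exactly one criterion.
    Returns (hits, go_annotations, go_dag_edges, coords) DataFrames.
    """
    rng = cfg.rng(_STREAM_ANNOT)
    hits = []
    for i, tid in enumerate(truth.transcript_ids):
        qlen = int(truth.lengths[tid])
        if tid in truth.cgt_transcripts:
            slen = int(rng.integers(600, 3000))
            hits.append(
                {
                    "qseqid": tid,
                    "sseqid": f"REFGENE{i:05d}",
                    "pident": round(float(rng.uniform(55, 95)), 1),
                    "length": int(rng.uniform(0.55, 0.95) * slen),
                    "evalue": float(10.0 ** rng.uniform(-50, -4)),
                    "qlen": qlen,
                    "slen": slen,
                }
            )
        elif rng.random() < 0.5:
            slen = int(rng.integers(600, 3000))
            fail = rng.integers(3)  # fail exactly one criterion
            evalue = float(10.0 ** rng.uniform(-50, -4))
            pident = round(float(rng.uniform(55, 95)), 1)
            cov = float(rng.uniform(0.55, 0.95))
            if fail == 0:
                evalue = float(10.0 ** rng.uniform(-2.9, 1.0))
            elif fail == 1:
                pident = round(float(rng.uniform(20, 49.5)), 1)
            else:
                cov = float(rng.uniform(0.05, 0.45))
            hits.append(
                {
                    "qseqid": tid,
                    "sseqid": f"REFGENE{i:05d}",
                    "pident": pident,
                    "length": int(cov * slen),
                    "evalue": evalue,
                    "qlen": qlen,
                    "slen": slen,
                }
            )
    hits_df = pd.DataFrame(hits)
    dag_df = _toy_go_dag()
    leaves = dag_df.attrs["leaves"]
    annot_rows = []
    for tid in truth.transcript_ids:
        k = int(rng.integers(1, 6))
        for term in rng.choice(leaves, size=min(k, len(leaves)), replace=False):
            annot_rows.append({"transcript": tid, "go_id": term})
    annot_df = pd.DataFrame(annot_rows)
    # populations on a latitudinal line, north group at high latitude
    lats = np.linspace(39.0, 24.5, cfg.n_pops)
    pops = cfg.pops_per_group["north"] + cfg.pops_per_group["south"]
    coords_df = pd.DataFrame(
        {"population": pops, "lat": lats.round(2), "lon": [121.0] * cfg.n_pops}
    )
    return hits_df, annot_df, dag_df, coords_df


@dataclass
class SimData:
    """Bundle of everything one simulated study comprises."""

    config: SimConfig
    truth: SimTruth
    genotypes: GenotypeTable
    expression: ExpressionTable
    popmap: PopMap
    hits: pd.DataFrame
    go_annotations: pd.DataFrame
    go_dag: pd.DataFrame
    coords: pd.DataFrame


def simulate_all(cfg: SimConfig) -> SimData:
    genotypes, truth = simulate_genotypes(cfg)
    expression = simulate_expression(cfg, truth)
    hits, annot, dag, coords = simulate_annotations(cfg, truth)
    return SimData(
        config=cfg,
        truth=truth,
        genotypes=genotypes,
        expression=expression,
        popmap=build_popmap(cfg),
        hits=hits,
        go_annotations=annot,
        go_dag=dag,
        coords=coords,
    )


def write_all(data: SimData, outdir) -> dict:
    """Write the full file contract; returns the path of each artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "snps.vcf",
        "counts": outdir / "counts.tsv",
        "fpkm": outdir / "fpkm.tsv",
        "popmap": outdir / "popmap.tsv",
        "hits": outdir / "hits.tsv",
        "go_annot": outdir / "go_annot.tsv",
        "go_dag": outdir / "go_dag.tsv",
        "coords": outdir / "coords.tsv",
    }
    io.write_vcf(
        data.genotypes,
        paths["vcf"],
        contig_lengths=data.truth.lengths.to_dict(),
    )
    io.write_matrix_tsv(data.expression.counts, paths["counts"])
    io.write_matrix_tsv(data.expression.fpkm, paths["fpkm"])
    data.popmap.write_tsv(paths["popmap"])
    data.hits.to_csv(paths["hits"], sep="\t", index=False)
    data.go_annotations.to_csv(paths["go_annot"], sep="\t", index=False)
    data.go_dag.to_csv(paths["go_dag"], sep="\t", index=False)
    data.coords.to_csv(paths["coords"], sep="\t", index=False)
    return paths
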