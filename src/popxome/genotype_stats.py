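"""SNP filtering, nucleotide diversity, Weir-Cockerham F_ST and genotype PCA.

Nucleotide diversity is computed per variant site and averaged per unigene
(transcript); invariant-site counts are unavailable for transcriptome-mapped
SNPs, so values are per-variant-site, not per-bp. F_ST follows the
Weir & Cockerham (1984) variance-component estimator with the multi-site
value taken as the ratio of summed components.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeTable, PairwiseMatrix, PCAResult, PopMap


def filter_snps(
    raw: GenotypeTable,
    max_missing: float = 0.5,
    min_depth: float = 6.0,
    min_maf: float = 0.02,
    min_qual: float = 10.0,
) -> GenotypeTable:
    """Retain biallelic SNPs passing missingness, depth, MAF and quality rules.

    A SNP survives when: biallelic; missing fraction <= max_missing; mean
    depth over non-missing calls >= min_depth; minor allele frequency over
    non-missing alleles >= min_maf; quality strictly greater than min_qual.
    Applied in that order; MAF is computed on the surviving calls only.
    """
    mask = np.ones(raw.n_snps, dtype=bool)
    biallelic = getattr(raw, "biallelic", None)
    if biallelic is not None:
        mask &= np.asarray(biallelic, dtype=bool)
    missing = raw.genotypes == MISSING
    miss_frac = missing.mean(axis=1)
    mask &= miss_frac <= max_missing
    if raw.depth is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            depth = np.where(missing, np.nan, raw.depth)
            mean_depth = np.nanmean(depth, axis=1)
        mask &= np.nan_to_num(mean_depth, nan=0.0) >= min_depth
    else:
        warnings.warn("no depth information; skipping the depth filter")
    n_called = (~missing).sum(axis=1)
    alt = np.where(missing, 0, raw.genotypes).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    mask &= np.nan_to_num(maf, nan=-1.0) >= min_maf
    mask &= np.nan_to_num(raw.qual, nan=np.inf) > min_qual
    out = raw.subset_snps(mask)
    if out.n_snps == 0:
        warnings.warn("no SNPs survived filtering")
    return out


def _allele_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (ref, alt) allele counts over non-missing calls."""
    called = genotypes != MISSING
    alt = np.where(called, genotypes, 0).sum(axis=1)
    total = 2 * called.sum(axis=1)
    return total - alt, alt


def nucleotide_diversity(g: GenotypeTable, popmap: PopMap) -> pd.DataFrame:
    """Per-transcript, per-population pi averaged over the variant sites.

    pi_site = 2 * c_ref * c_alt / (m * (m - 1)) with m non-missing alleles
    in the population; the unigene value is the arithmetic mean over its
    variant sites. Populations with fewer than two called alleles at every
    site of a transcript are omitted.
    """
    records = []
    for pop in popmap.populations:
        cols = g.columns_for(popmap.members(pop))
        sub = g.genotypes[:, cols]
        c_ref, c_alt = _allele_counts(sub)
        m = c_ref + c_alt
        with np.errstate(divide="ignore", invalid="ignore"):
            pi_site = np.where(m >= 2, 2.0 * c_ref * c_alt / (m * (m - 1.0)), np.nan)
        df = pd.DataFrame({"transcript": g.transcript_ids, "pi_site": pi_site})
        grouped = df.groupby("transcript", sort=True)["pi_site"].agg(["mean", "count"])
        grouped = grouped[grouped["count"] >= 1]
        for tid, row in grouped.iterrows():
            records.append(
                {
                    "transcript": tid,
                    "population": pop,
                    "pi": float(row["mean"]),
                    "n_sites": int(row["count"]),
                }
            )
    return pd.DataFrame(records, columns=["transcript", "population", "pi", "n_sites"])


def weir_cockerham_components(
    genotypes: np.ndarray, unit_columns: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham (a, b, c) variance components over r units.

    ``unit_columns`` are column-index arrays, one per population (or group).
    Sites where fewer than two units have called genotypes, or with n_bar <= 1,
    yield NaN components and are ignored by the ratio.
    """
    r = len(unit_columns)
    n_sites = genotypes.shape[0]
    n_i = np.zeros((r, n_sites))
    p_i = np.zeros((r, n_sites))
    h_i = np.zeros((r, n_sites))
    for k, cols in enumerate(unit_columns):
        sub = genotypes[:, cols]
        called = sub != MISSING
        n = called.sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(called, sub, 0).sum(axis=1) / (2.0 * n)
            h = np.where(called & (sub == 1), 1, 0).sum(axis=1) / n
        n_i[k] = n
        p_i[k] = p
        h_i[k] = h
    valid = (n_i > 0).sum(axis=0) >= 2
    n_i = np.where(n_i > 0, n_i, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_eff = np.sum(~np.isnan(n_i), axis=0).astype(float)
        n_sum = np.nansum(n_i, axis=0)
        n_bar = n_sum / r_eff
        nc = (n_sum - np.nansum(n_i**2, axis=0) / n_sum) / (r_eff - 1.0)
        p_bar = np.nansum(n_i * p_i, axis=0) / n_sum
        s2 = np.nansum(n_i * (p_i - p_bar) ** 2, axis=0) / ((r_eff - 1.0) * n_bar)
        h_bar = np.nansum(n_i * h_i, axis=0) / n_sum
        inner = p_bar * (1 - p_bar) - (r_eff - 1.0) / r_eff * s2 - h_bar / 4.0
        a = (n_bar / nc) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar)
            - (r_eff - 1.0) / r_eff * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    bad = ~valid | (n_bar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def multilocus_fst(genotypes: np.ndarray, unit_columns: list[np.ndarray]) -> float:
    """Ratio-of-sums Weir-Cockerham F_ST over all usable sites."""
    a, b, c = weir_cockerham_components(genotypes, unit_columns)
    usable = ~np.isnan(a)
    denom = np.nansum(a[usable] + b[usable] + c[usable])
    if not usable.any() or denom == 0:
        return float("nan")
    return float(np.nansum(a[usable]) / denom)


def pairwise_fst(g: GenotypeTable, popmap: PopMap, level: str = "population") -> PairwiseMatrix:
    """Pairwise multi-site Weir-Cockerham F_ST between populations or groups.

    At group level each group is one unit (its populations pooled), matching
    a two-group north/south contrast. Small negative values are possible and
    reported as-is.
    """
    units = popmap.units(level)
    if len(units) < 2:
        raise ValueError("need at least two units for pairwise F_ST")
    cols = {}
    for unit in units:
        c = g.columns_for(popmap.members(unit, level))
        if (g.genotypes[:, c] == MISSING).all():
            raise ValueError(f"unit {unit!r} has no called genotypes")
        cols[unit] = c
    n = len(units)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fst = multilocus_fst(g.genotypes, [cols[units[i]], cols[units[j]]])
            mat[i, j] = mat[j, i] = min(fst, 1.0)
    return PairwiseMatrix(labels=list(units), values=mat, kind="distance")


def _orient_components(coords: np.ndarray) -> np.ndarray:
    # sign convention: the largest-magnitude entry of each component positive
    for k in range(coords.shape[1]):
        col = coords[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    return coords


def genotype_pca(g: GenotypeTable, n_components: int = 10) -> PCAResult:
    """PCA of the standardized alt-allele dosage matrix.

    Missing entries are imputed with the SNP mean dosage; columns are
    centered and scaled by sqrt(2 p (1-p)) with p the alt-allele frequency
    estimate (monomorphic SNPs contribute zero); components come from the
    eigendecomposition of the individual-by-individual covariance.
    """
    n_ind = g.n_individuals
    if n_components > n_ind - 1:
        raise ValueError("n_components must be at most individuals - 1")
    d = g.dosage_matrix()  # individuals x SNPs, NaN missing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    p_hat = col_mean / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    centered = d - col_mean
    nz = scale > 0
    centered[:, nz] /= scale[nz]
    centered[:, ~nz] = 0.0
    cov = centered @ centered.T / max(centered.shape[1], 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    total = eigval.sum()
    evr = eigval / total if total > 0 else np.zeros_like(eigval)
    coords = _orient_components(eigvec[:, :n_components] * np.sqrt(eigval[:n_components]))
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=g.individuals, columns=cols),
        explained_variance_ratio=evr,
    )
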