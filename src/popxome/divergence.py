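"""Differential expression and highly divergent (HD) transcript calling.

The DE stage is a self-contained negative-binomial Wald test in the DESeq2
mould — median-of-ratios size factors, method-of-moments dispersion, Wald
test on the log2 ratio of normalized group means, Benjamini-Hochberg
adjustment — deliberately without dispersion or fold-change shrinkage: the
pipeline's claims concern the procedure, not numerical identity with any
particular DE package.

The HD stage is a DAPC: PCA of the dosage matrix retaining >99% of the
variance, a linear discriminant between the two predefined groups in PC
space, and per-SNP allele loadings from the back-projected discriminant
axis; the top 10% of loadings mark HD SNPs, and a transcript containing at
least one HD SNP is an HD transcript.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeTable, PopMap

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    The reference uses only transcripts with no zero count in any library.
    """
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts.to_numpy(dtype=float))
    all_positive = np.isfinite(log_counts).all(axis=1)
    if not all_positive.any():
        raise ValueError("no transcript has positive counts in every library")
    log_ref = log_counts[all_positive].mean(axis=1)
    ratios = log_counts[all_positive] - log_ref[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def de_test(
    counts: pd.DataFrame,
    popmap: PopMap,
    alpha: float = 0.05,
    fold_change: float = 1.5,
    north: str = "north",
    south: str = "south",
) -> pd.DataFrame:
    """NB Wald test of south-vs-north expression per transcript.

    Returns one row per tested transcript: log2fc (south over north, with a
    0.5 pseudo-count on normalized means), raw and BH-adjusted p-values,
    is_de (padj < alpha AND |log2fc| > log2(fold_change)) and the direction
    label ('south-up' / 'north-up', defined only for DE calls). All-zero
    transcripts are excluded and reported via the 'tested' column of
    attrs['excluded'].
    """
    groups = popmap.groups
    if set((north, south)) - set(groups):
        raise ValueError(f"popmap must define groups {north!r} and {south!r}")
    cols_n = [m for m in popmap.members(north, "group") if m in counts.columns]
    cols_s = [m for m in popmap.members(south, "group") if m in counts.columns]
    if len(cols_n) < 3 or len(cols_s) < 3:
        raise ValueError("each group needs at least three individuals")
    nonzero = counts[cols_n + cols_s].sum(axis=1) > 0
    excluded = list(counts.index[~nonzero])
    cts = counts.loc[nonzero, cols_n + cols_s]
    sf = size_factors(cts)
    q = cts / sf
    qn = q[cols_n].to_numpy()
    qs = q[cols_s].to_numpy()
    m_n = qn.mean(axis=1)
    m_s = qs.mean(axis=1)
    # method-of-moments dispersion from pooled within-group variance of
    # normalized counts, floored; the group effect must not inflate it
    n_n, n_s = len(cols_n), len(cols_s)
    var_within = (
        qn.var(axis=1, ddof=1) * (n_n - 1) + qs.var(axis=1, ddof=1) * (n_s - 1)
    ) / (n_n + n_s - 2)
    m_all = q.to_numpy().mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (var_within - m_all) / np.square(m_all)
    disp = np.clip(np.nan_to_num(disp, nan=DISPERSION_FLOOR), DISPERSION_FLOOR, None)
    lfc = np.log2(m_s + PSEUDOCOUNT) - np.log2(m_n + PSEUDOCOUNT)
    inv_sf = (1.0 / sf).to_numpy()
    inv_n = inv_sf[: n_n].sum() / n_n**2
    inv_s = inv_sf[n_n:].sum() / n_s**2
    # delta method on log2 of the NB group means (var(q_ij) = m/sf_j + disp m^2)
    var_mean_n = m_n * inv_n + disp * np.square(m_n) / n_n
    var_mean_s = m_s * inv_s + disp * np.square(m_s) / n_s
    ln2sq = math.log(2.0) ** 2
    se = np.sqrt(
        var_mean_n / (np.square(m_n + PSEUDOCOUNT) * ln2sq)
        + var_mean_s / (np.square(m_s + PSEUDOCOUNT) * ln2sq)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    padj = multipletests(pvals, method="fdr_bh")[1]
    is_de = (padj < alpha) & (np.abs(lfc) > math.log2(fold_change))
    direction = np.where(is_de, np.where(lfc > 0, "south-up", "north-up"), "")
    out = pd.DataFrame(
        {
            "transcript": cts.index,
            "base_mean": q.to_numpy().mean(axis=1),
            "log2fc": lfc,
            "pvalue": pvals,
            "padj": padj,
            "is_de": is_de,
            "direction": direction,
        }
    ).set_index("transcript")
    out.attrs["excluded"] = excluded
    out.attrs["size_factors"] = sf
    return out


def dapc_loadings(
    g: GenotypeTable,
    popmap: PopMap,
    var_retained: float = 0.99,
    top_frac: float = 0.1,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Per-SNP allele loadings from a two-group DAPC.

    Dosage matrix mean-imputed and centered; PCA keeps the minimal number
    of components whose cumulative explained variance exceeds
    ``var_retained``; a linear discriminant between the two groups uses the
    pooled within-group covariance in PC space (ridge-regularized); the
    loading of a SNP is the squared back-projected discriminant coefficient,
    normalized to sum to one. The top ``top_frac`` of loadings (ceiling
    count, ties broken by SNP ID) are flagged HD.
    """
    groups = popmap.groups
    if len(groups) != 2:
        raise ValueError("DAPC loadings require exactly two groups")
    cols = {grp: g.columns_for(popmap.members(grp, "group")) for grp in groups}
    for grp, c in cols.items():
        if len(c) < 2:
            raise ValueError(f"group {grp!r} needs at least two individuals")
    d = g.dosage_matrix()  # individuals x SNPs
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    centered = d - d.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    nonzero = s > s[0] * 1e-12 if s.size and s[0] > 0 else s > 0
    s = s[nonzero]
    u = u[:, nonzero]
    vt = vt[nonzero]
    var = s**2
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, var_retained, side="right")) + 1
    k = min(k, len(s))
    scores = u[:, :k] * s[:k]
    rot = vt[:k].T  # SNPs x k
    mu = {grp: scores[c].mean(axis=0) for grp, c in cols.items()}
    n1, n2 = (len(cols[grp]) for grp in groups)
    w = (
        np.cov(scores[cols[groups[0]]].T, ddof=1) * (n1 - 1)
        + np.cov(scores[cols[groups[1]]].T, ddof=1) * (n2 - 1)
    ) / (n1 + n2 - 2)
    w = np.atleast_2d(w) + ridge * np.eye(k)
    direction = np.linalg.solve(w, mu[groups[0]] - mu[groups[1]])
    beta = rot @ direction  # back-projected discriminant coefficients per SNP
    loading = np.square(beta)
    total = loading.sum()
    if total > 0:
        loading = loading / total
    is_hd = top_loading_mask(loading, g.snp_ids, top_frac)
    return pd.DataFrame(
        {
            "snp": g.snp_ids,
            "transcript": g.transcript_ids,
            "loading": loading,
            "is_hd": is_hd,
        }
    )


def top_loading_mask(loadings: np.ndarray, snp_ids: np.ndarray, top_frac: float = 0.1) -> np.ndarray:
    """Boolean mask of the top ceil(top_frac * n) loadings.

    Sort is by loading descending, ties broken by SNP ID order, so the
    selected count is exact.
    """
    n = len(loadings)
    n_top = math.ceil(top_frac * n)
    order = sorted(range(n), key=lambda i: (-loadings[i], str(snp_ids[i])))
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_top]] = True
    return mask


def hd_transcripts(calls: pd.DataFrame) -> set:
    """Transcripts containing at least one HD SNP."""
    return set(calls.loc[calls["is_hd"], "transcript"])
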