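"""FPKM filtering, Ep/Ed statistics, expression similarity and PCA.

Ep (population expression) is the mean FPKM of a transcript over a
population's individuals; Ed (expression diversity) is the mean absolute
deviation from Ep normalized by (n-1)*Ep, a dimensionless, scale-invariant
spread measure. The dispersion comparison contrasts candidate-gene and
non-candidate transcripts on their coefficient of variation.
"""
from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionTable, PairwiseMatrix, PCAResult, PopMap, TestResult
from .genotype_stats import _orient_components


def filter_expression(
    x: ExpressionTable,
    popmap: PopMap,
    mean_floor: float = 4.0,
    scope: str = "population",
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Drop low or highly variable transcripts.

    A transcript is removed if, in ANY population, the mean FPKM over that
    population's libraries is below ``mean_floor`` OR the standard deviation
    exceeds the mean. With ``scope='global'`` the SD is taken over all
    libraries instead and compared against each population's mean.
    Populations of size one have no SD; that criterion is skipped for them.
    Returns the filtered table and a per-transcript report of pass flags.
    """
    if scope not in ("population", "global"):
        raise ValueError("scope must be 'population' or 'global'")
    fpkm = x.fpkm
    report = pd.DataFrame(index=fpkm.index)
    keep = pd.Series(True, index=fpkm.index)
    global_sd = fpkm.std(axis=1, ddof=1)
    for pop in popmap.populations:
        members = [m for m in popmap.members(pop) if m in fpkm.columns]
        sub = fpkm[members]
        mean = sub.mean(axis=1)
        ok = mean >= mean_floor
        if len(members) >= 2:
            sd = global_sd if scope == "global" else sub.std(axis=1, ddof=1)
            ok &= sd <= mean
        else:
            warnings.warn(f"population {pop!r} has one library; SD criterion skipped")
        report[f"pass_{pop}"] = ok
        keep &= ok
    report["retained"] = keep
    kept = x.subset_transcripts(fpkm.index[keep])
    return kept, report


def population_expression(x: ExpressionTable, popmap: PopMap) -> pd.DataFrame:
    """Ep = mean FPKM per transcript per population."""
    records = []
    for pop in popmap.populations:
        members = [m for m in popmap.members(pop) if m in x.fpkm.columns]
        ep = x.fpkm[members].mean(axis=1)
        for tid, value in ep.items():
            records.append(
                {"transcript": tid, "population": pop, "n": len(members), "Ep": float(value)}
            )
    return pd.DataFrame(records)


def expression_diversity(x: ExpressionTable, popmap: PopMap) -> pd.DataFrame:
    """Ed = sum|Ei - Ep| / ((n-1) * Ep) per transcript per population.

    Ed is NaN (flagged missing) when Ep = 0 or n < 2; downstream
    correlations drop those records.
    """
    records = []
    for pop in popmap.populations:
        members = [m for m in popmap.members(pop) if m in x.fpkm.columns]
        sub = x.fpkm[members]
        n = len(members)
        ep = sub.mean(axis=1)
        if n >= 2:
            with np.errstate(divide="ignore", invalid="ignore"):
                ed = sub.sub(ep, axis=0).abs().sum(axis=1) / ((n - 1) * ep)
            ed = ed.where(ep > 0)
        else:
            ed = pd.Series(np.nan, index=sub.index)
        for tid in sub.index:
            records.append(
                {
                    "transcript": tid,
                    "population": pop,
                    "n": n,
                    "Ep": float(ep[tid]),
                    "Ed": float(ed[tid]) if pd.notna(ed[tid]) else np.nan,
                }
            )
    return pd.DataFrame(records)


def _log_profiles(x: ExpressionTable) -> pd.DataFrame:
    return np.log2(x.fpkm + 1.0)


def ep_similarity(
    x: ExpressionTable,
    popmap: PopMap,
    pop_a: str,
    pop_b: str,
    mode: str = "pairwise",
) -> TestResult:
    """Expression similarity between two populations.

    ``pairwise`` (default): mean Pearson r over every cross-population
    individual pair, computed on log2(FPKM+1) profiles; ``ep-vector``:
    Pearson r between the two populations' log2(Ep+1) vectors.
    """
    if mode not in ("pairwise", "ep-vector"):
        raise ValueError("mode must be 'pairwise' or 'ep-vector'")
    logf = _log_profiles(x)
    a = [m for m in popmap.members(pop_a) if m in logf.columns]
    b = [m for m in popmap.members(pop_b) if m in logf.columns]
    if len(logf.index) < 2:
        raise ValueError("need at least two shared transcripts")
    if mode == "ep-vector":
        va = logf[a].mean(axis=1)
        vb = logf[b].mean(axis=1)
        r = float(stats.pearsonr(va, vb).statistic)
        return TestResult("ep_similarity", r, n=len(va), metadata={"mode": mode})
    rs = []
    for i, j in itertools.product(a, b):
        vi, vj = logf[i].to_numpy(), logf[j].to_numpy()
        if np.ptp(vi) == 0 or np.ptp(vj) == 0:
            warnings.warn(f"constant profile in pair ({i}, {j}); skipped")
            continue
        rs.append(stats.pearsonr(vi, vj).statistic)
    if not rs:
        raise ValueError("no usable individual pairs")
    return TestResult(
        "ep_similarity", float(np.mean(rs)), n=len(rs), metadata={"mode": mode}
    )


def ep_similarity_matrix(
    x: ExpressionTable, popmap: PopMap, mode: str = "pairwise"
) -> PairwiseMatrix:
    """All-pairs Ep similarity (unit diagonal)."""
    pops = popmap.populations
    n = len(pops)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = ep_similarity(x, popmap, pops[i], pops[j], mode=mode).estimate
            mat[i, j] = mat[j, i] = r
    return PairwiseMatrix(labels=list(pops), values=mat, kind="similarity")


def expression_pca(x: ExpressionTable, n_components: int = 10) -> PCAResult:
    """PCA of individuals over log2(FPKM+1), transcript-centered."""
    logf = _log_profiles(x)
    m = logf.to_numpy().T  # individuals x transcripts
    if n_components > m.shape[0] - 1:
        raise ValueError("n_components must be at most individuals - 1")
    centered = m - m.mean(axis=0, keepdims=True)
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
        coordinates=pd.DataFrame(coords, index=list(logf.columns), columns=cols),
        explained_variance_ratio=evr,
    )


def dispersion_comparison(
    x: ExpressionTable,
    cgt_flags: pd.Series,
    min_expressed_frac: float = 0.5,
) -> TestResult:
    """Welch t-test of log dispersion coefficients, CGT vs non-CGT.

    The dispersion coefficient of a transcript is its coefficient of
    variation (SD/mean) of FPKM over all individuals; only transcripts
    expressed (FPKM > 0) in more than ``min_expressed_frac`` of samples
    enter, and zero-mean transcripts are excluded. The test is run on
    natural-log CVs; reported group means are on the raw CV scale.
    """
    fpkm = x.fpkm
    expressed = (fpkm > 0).mean(axis=1) > min_expressed_frac
    mean = fpkm.mean(axis=1)
    usable = expressed & (mean > 0)
    cv = fpkm.std(axis=1, ddof=1)[usable] / mean[usable]
    flags = cgt_flags.reindex(cv.index).fillna(False).astype(bool)
    cv_cgt = cv[flags]
    cv_non = cv[~flags]
    if cv_cgt.empty or cv_non.empty:
        raise ValueError("both CGT and non-CGT sets must be non-empty after filtering")
    log_cgt = np.log(cv_cgt[cv_cgt > 0])
    log_non = np.log(cv_non[cv_non > 0])
    res = stats.ttest_ind(log_cgt, log_non, equal_var=False)
    t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return TestResult(
        name="dispersion_comparison",
        estimate=float(cv_cgt.mean() - cv_non.mean()),
        statistic=t_stat,
        pvalue=p,
        n=int(len(cv_cgt) + len(cv_non)),
        metadata={
            "mean_cv_cgt": float(cv_cgt.mean()),
            "mean_cv_non_cgt": float(cv_non.mean()),
            "df": df,
            "n_cgt": int(len(cv_cgt)),
            "n_non_cgt": int(len(cv_non)),
        },
    )
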