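"""Geography, Mantel tests, Ed-pi correlations and north-south comparisons.

Distances are haversine great circles; Mantel tests permute one matrix's
rows and columns jointly and are one-sided for positive association (the
isolation-by-distance convention); diversity correlations relate expression
diversity (Ed) to nucleotide diversity (pi) within and across populations;
the paired group comparison is a Wilcoxon signed-rank test over transcripts
paired by group-mean values.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PairwiseMatrix, TestResult

EARTH_RADIUS_KM = 6371.0088


def geographic_distance(coords: pd.DataFrame) -> PairwiseMatrix:
    """Haversine great-circle distances (km) between populations."""
    lat = coords["lat"].to_numpy(dtype=float)
    lon = coords["lon"].to_numpy(dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValueError("latitude must be in [-90, 90] and longitude in [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return PairwiseMatrix(labels=list(coords["population"]), values=d, kind="distance")


def similarity_to_distance(m: PairwiseMatrix) -> PairwiseMatrix:
    """1 - r conversion of a similarity matrix (zero diagonal)."""
    values = 1.0 - m.values
    np.fill_diagonal(values, 0.0)
    return PairwiseMatrix(labels=list(m.labels), values=values, kind="distance")


def mantel_test(
    m1: PairwiseMatrix,
    m2: PairwiseMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> TestResult:
    """One-sided (positive-association) Mantel permutation test.

    r is the Pearson correlation of the upper triangles; the permutation
    distribution jointly relabels rows and columns of the second matrix;
    p = (#{permuted r >= observed} + 1) / (n_perm + 1).
    """
    if m1.kind == "similarity" or m2.kind == "similarity":
        raise ValueError("convert similarity matrices to distances first")
    if set(m1.labels) != set(m2.labels):
        raise ValueError("matrices must share labels")
    n = len(m1.labels)
    if n < 3:
        raise ValueError("Mantel test needs at least three labels")
    m2 = m2.reorder(m1.labels)
    iu = np.triu_indices(n, k=1)
    x = m1.values[iu]
    y_mat = m2.values

    def corr(values: np.ndarray) -> float:
        return float(stats.pearsonr(x, values[iu]).statistic)

    observed = corr(y_mat)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(y_mat[np.ix_(perm, perm)]) >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return TestResult(
        name="mantel",
        estimate=observed,
        statistic=observed,
        pvalue=p,
        n=n_perm,
        metadata={"n_labels": n, "seed": seed, "alternative": "greater"},
    )


def diversity_correlation(
    ed: pd.DataFrame,
    pi: pd.DataFrame,
    scope: str = "within",
) -> list[TestResult]:
    """Pearson correlation of Ed and pi over shared transcripts.

    ``within``: one correlation per population over transcripts with both
    values; ``across``: one correlation of population-mean Ed against
    population-mean pi. p-values come from the t distribution.
    """
    if scope not in ("within", "across"):
        raise ValueError("scope must be 'within' or 'across'")
    merged = ed.merge(pi, on=["transcript", "population"], suffixes=("_ed", "_pi"))
    merged = merged.dropna(subset=["Ed", "pi"])
    if merged.empty:
        raise ValueError("no shared transcripts between Ed and pi tables")
    results = []
    if scope == "within":
        for pop, sub in merged.groupby("population", sort=True):
            if len(sub) < 3:
                raise ValueError(f"population {pop!r} has fewer than 3 shared transcripts")
            r = stats.pearsonr(sub["Ed"], sub["pi"])
            results.append(
                TestResult(
                    name="ed_pi_correlation",
                    estimate=float(r.statistic),
                    statistic=float(r.statistic),
                    pvalue=float(r.pvalue),
                    n=len(sub),
                    metadata={"population": pop, "scope": scope},
                )
            )
    else:
        means = merged.groupby("population", sort=True)[["Ed", "pi"]].mean()
        if len(means) < 3:
            raise ValueError("need at least 3 populations for an across-population correlation")
        r = stats.pearsonr(means["Ed"], means["pi"])
        results.append(
            TestResult(
                name="ed_pi_correlation",
                estimate=float(r.statistic),
                statistic=float(r.statistic),
                pvalue=float(r.pvalue),
                n=len(means),
                metadata={"scope": scope},
            )
        )
    return results


def paired_group_comparison(
    values_north: pd.Series,
    values_south: pd.Series,
    statistic: str = "pi",
) -> TestResult:
    """Wilcoxon signed-rank test of south vs north, paired per transcript.

    Inputs are group-level values indexed by transcript (group value = mean
    over the group's populations); zero differences are dropped; the exact
    null distribution is used for small samples without ties and the
    tie-corrected normal approximation otherwise (two-sided).
    """
    shared = values_north.index.intersection(values_south.index)
    vn = values_north.loc[shared].astype(float)
    vs = values_south.loc[shared].astype(float)
    mask = vn.notna() & vs.notna()
    vn, vs = vn[mask], vs[mask]
    diff = vs - vn
    if (diff == 0).all():
        warnings.warn("all paired differences are zero")
        return TestResult(
            name=f"wilcoxon_{statistic}",
            estimate=0.0,
            statistic=0.0,
            pvalue=1.0,
            n=len(diff),
            metadata={"direction": "equal", "statistic": statistic},
        )
    res = stats.wilcoxon(vs, vn, zero_method="wilcox", alternative="two-sided", method="auto")
    med_n, med_s = float(vn.median()), float(vs.median())
    direction = "south-higher" if med_s > med_n else ("north-higher" if med_n > med_s else "equal")
    if med_s == med_n:
        direction = "south-higher" if diff.median() > 0 else "north-higher"
    return TestResult(
        name=f"wilcoxon_{statistic}",
        estimate=float(diff.median()),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n=int((diff != 0).sum()),
        metadata={
            "median_north": med_n,
            "median_south": med_s,
            "direction": direction,
            "statistic": statistic,
        },
    )


def group_mean_values(per_population: pd.DataFrame, popmap, column: str) -> pd.DataFrame:
    """Transcript x group matrix of group-mean values from per-population rows."""
    df = per_population.copy()
    df["group"] = df["population"].map(
        dict(zip(popmap.table["population"], popmap.table["group"]))
    )
    return df.pivot_table(index="transcript", columns="group", values=column, aggfunc="mean")
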