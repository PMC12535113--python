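"""Candidate-gene transcript (CGT) classification and over-representation.

A transcript is a CGT when a homology hit against the curated reference
candidate genes passes all of: e-value < 1e-3, identity > 50%, and
alignment length > 50% of the reference (subject) gene length. CGT
over-representation among DAPC-divergent and differentially expressed
transcripts is assessed with upper-tail hypergeometric tests, Bonferroni
corrected over the tests executed in the run.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def classify_cgt(
    hits: pd.DataFrame,
    transcripts: list[str],
    max_evalue: float = 1e-3,
    min_identity: float = 50.0,
    min_coverage: float = 0.5,
    coverage_basis: str = "subject",
) -> pd.DataFrame:
    """Per-transcript CGT flag plus the best passing hit.

    All three criteria are strict inequalities (a hit at e-value exactly
    1e-3 or identity exactly 50 fails). Coverage = alignment length divided
    by the subject (reference gene) length by default; ``coverage_basis=
    'query'`` divides by the transcript length instead. The best hit is the
    passing hit with the smallest e-value, ties broken by highest identity
    then subject ID order.
    """
    if coverage_basis not in ("subject", "query"):
        raise ValueError("coverage_basis must be 'subject' or 'query'")
    known = set(transcripts)
    unknown = set(hits["qseqid"]) - known
    if unknown:
        warnings.warn(f"{len(unknown)} hits reference unknown transcripts; skipped")
        hits = hits[hits["qseqid"].isin(known)]
    denom = hits["slen"] if coverage_basis == "subject" else hits["qlen"]
    coverage = hits["length"] / denom
    passing = hits.loc[
        (hits["evalue"] < max_evalue)
        & (hits["pident"] > min_identity)
        & (coverage > min_coverage)
    ].copy()
    passing["coverage"] = coverage.loc[passing.index]
    passing = passing.sort_values(
        ["qseqid", "evalue", "pident", "sseqid"], ascending=[True, True, False, True]
    )
    best = passing.groupby("qseqid", sort=False).first()
    records = []
    for tid in transcripts:
        if tid in best.index:
            row = best.loc[tid]
            records.append(
                {
                    "transcript": tid,
                    "is_cgt": True,
                    "best_subject": row["sseqid"],
                    "best_evalue": float(row["evalue"]),
                    "best_identity": float(row["pident"]),
                    "best_coverage": float(row["coverage"]),
                }
            )
        else:
            records.append(
                {
                    "transcript": tid,
                    "is_cgt": False,
                    "best_subject": None,
                    "best_evalue": np.nan,
                    "best_identity": np.nan,
                    "best_coverage": np.nan,
                }
            )
    return pd.DataFrame(records).set_index("transcript")


@dataclass
class EnrichmentResult:
    """One over-representation analysis (one row of the report table)."""

    label: str
    input_total: int
    input_cgt: int
    output_total: int
    output_cgt: int
    p_raw: Optional[float] = None
    p_bonferroni: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.output_cgt <= min(self.output_total, self.input_cgt)):
            raise ValueError("output CGT count out of bounds")
        if self.output_total > self.input_total or self.input_cgt > self.input_total:
            raise ValueError("output/CGT totals exceed the input universe")

    @property
    def input_pct(self) -> float:
        return 100.0 * self.input_cgt / self.input_total

    @property
    def output_pct(self) -> Optional[float]:
        if self.output_total == 0:
            return None
        return 100.0 * self.output_cgt / self.output_total

    @property
    def diff_pct(self) -> Optional[float]:
        if self.output_pct is None:
            return None
        return abs(self.output_pct - self.input_pct)

    def report_row(self) -> dict:
        out_pct = self.output_pct
        return {
            "analysis": self.label,
            "input_total": self.input_total,
            "input_cgt": self.input_cgt,
            "output_total": self.output_total,
            "output_cgt": self.output_cgt,
            "input_pct": _round_half_up(self.input_pct),
            "output_pct": None if out_pct is None else _round_half_up(out_pct),
            "diff_pct": None if self.diff_pct is None else _round_half_up(self.diff_pct),
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_bonferroni,
        }


def proportion_table(entries: list[EnrichmentResult]) -> pd.DataFrame:
    """Report table of CGT input/output percentages and their differences.

    Percentages are rounded half-up to one decimal for the report; the raw
    counts stay in the table unrounded. Empty output sets are flagged with
    missing percentages.
    """
    rows = []
    for e in entries:
        if e.output_total == 0:
            warnings.warn(f"analysis {e.label!r} has an empty output set")
        rows.append(e.report_row())
    return pd.DataFrame(rows)


def hypergeom_overrep(
    input_total: int,
    input_cgt: int,
    output_total: int,
    output_cgt: int,
    n_tests: int = 1,
    label: str = "enrichment",
) -> EnrichmentResult:
    """Upper-tail hypergeometric over-representation test.

    p_raw = P(X >= output_cgt) with X ~ Hypergeom(N=input_total,
    K=input_cgt, n=output_total); Bonferroni multiplies by ``n_tests``
    (capped at 1).
    """
    result = EnrichmentResult(label, input_total, input_cgt, output_total, output_cgt)
    p_raw = float(stats.hypergeom.sf(output_cgt - 1, input_total, input_cgt, output_total))
    result.p_raw = p_raw
    result.p_bonferroni = min(1.0, p_raw * n_tests)
    return result


def enrichment_analysis(
    cgt: pd.DataFrame,
    de_calls: pd.DataFrame,
    hd_set: set,
    dapc_universe: list[str],
    de_universe: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Full Table-style over-representation report for one pipeline run.

    Five analyses: DAPC (HD transcripts) plus the four direction-specific
    DE categories. In a two-group contrast a transcript up in the north is
    the same transcript down in the south, so the Nor-up/Sou-down (and
    Sou-up/Nor-down) rows share counts. Only over-representation is tested
    (upper tail); under-represented rows show p near 1 by construction.
    """
    is_cgt = cgt["is_cgt"]
    if de_universe is None:
        de_universe = list(de_calls.index)
    de_universe = list(de_universe)

    def cgt_count(transcripts) -> int:
        return int(is_cgt.reindex(list(transcripts)).fillna(False).sum())

    north_up = set(de_calls.index[(de_calls["is_de"]) & (de_calls["direction"] == "north-up")])
    south_up = set(de_calls.index[(de_calls["is_de"]) & (de_calls["direction"] == "south-up")])
    analyses = [
        ("DAPC", dapc_universe, hd_set),
        ("DE Nor up", de_universe, north_up),
        ("DE Sou up", de_universe, south_up),
        ("DE Nor down", de_universe, south_up),
        ("DE Sou down", de_universe, north_up),
    ]
    n_tests = len(analyses)
    results = []
    for label, universe, output in analyses:
        results.append(
            hypergeom_overrep(
                input_total=len(universe),
                input_cgt=cgt_count(universe),
                output_total=len(output),
                output_cgt=cgt_count(output),
                n_tests=n_tests,
                label=label,
            )
        )
    return proportion_table(results)
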