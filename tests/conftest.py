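import numpy as np
import pandas as pd
import pytest

from popxome.containers import ExpressionTable, GenotypeTable, PopMap
from popxome.synthetic_data import SimConfig, build_popmap, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """One small full dataset shared by read-only tests."""
    cfg = SimConfig(n_transcripts=300, snps_per_transcript=4, seed=101)
    return simulate_all(cfg)


@pytest.fixture
def two_pop_map():
    rows = []
    for pop, group in [("N1", "north"), ("S1", "south")]:
        for k in range(10):
            rows.append({"individual": f"{pop}_{k:02d}", "population": pop, "group": group})
    return PopMap(pd.DataFrame(rows))


def make_genotypes(genotypes, individuals, transcripts=None, qual=None, depth=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n = genotypes.shape[0]
    if transcripts is None:
        transcripts = [f"TR{i:03d}" for i in range(n)]
    return GenotypeTable(
        genotypes=genotypes,
        snp_ids=np.array([f"snp{i}" for i in range(n)], dtype=object),
        transcript_ids=np.asarray(transcripts, dtype=object),
        individuals=list(individuals),
        qual=np.full(n, 99.0) if qual is None else np.asarray(qual, dtype=float),
        depth=depth,
    )


def make_expression(values, individuals, transcripts=None, counts=None):
    values = np.asarray(values, dtype=float)
    if transcripts is None:
        transcripts = [f"T{i}" for i in range(values.shape[0])]
    fpkm = pd.DataFrame(values, index=transcripts, columns=list(individuals))
    cts = None
    if counts is not None:
        cts = pd.DataFrame(np.asarray(counts), index=transcripts, columns=list(individuals))
    return ExpressionTable(fpkm=fpkm, counts=cts)
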