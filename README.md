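# popxome

Joint sequence and expression divergence analysis for population
transcriptomics along environmental gradients.

When a widespread species spans an environmental cline (for example a
latitudinal thermal gradient), local adaptation can act on gene sequences,
on gene expression, or on both. `popxome` implements a comparative
population-transcriptomics pipeline for detecting and interpreting such
concerted divergence between two predefined groups of populations
("north" vs "south"), together with a reverse-ecology layer that asks
whether transcripts orthologous to curated candidate genes (e.g.
temperature-relevance genes) are over-represented among the diverged ones.

It is aimed at molecular ecologists working from a transcriptome-mapped SNP
call set (VCF), FPKM/count expression matrices, and a homology table against
a curated candidate-gene list — typically for non-model organisms with no
reference genome.

## What it computes

**Sequence side** (`genotype_stats`, `divergence`)

- SNP filtering: biallelic, missingness ≤ 50%, mean depth ≥ 6, MAF ≥ 0.02,
  quality > 10.
- Nucleotide diversity π per unigene and population: per variant site,
  π = 2·c_ref·c_alt / (m(m−1)); per-unigene value is the mean over variant
  sites.
- Pairwise Weir–Cockerham (1984) *F*_ST between populations or groups, as
  the ratio of summed per-site variance components a / (a+b+c).
- Genotype PCA on standardized alt-allele dosages (scaled by √(2p̂(1−p̂))).
- DAPC allele loadings: PCA retaining > 99% of variance, a linear
  discriminant between the two groups, per-SNP loadings from the squared
  back-projected discriminant axis; the top 10% of loadings (ceiling count)
  mark "highly divergent" (HD) SNPs, and any transcript containing one is
  an HD transcript.

**Expression side** (`expression_stats`, `divergence`)

- Transcript filter: removed if, in any population, mean FPKM < 4 or the
  SD exceeds the mean.
- Population expression Ep = ΣEi/n and expression diversity
  Ed = Σ|Ei − Ep| / ((n−1)·Ep) — a dimensionless, scale-invariant spread.
- Ep similarity between populations: mean Pearson *r* over cross-population
  individual pairs on log2(FPKM+1) profiles; expression PCA likewise on
  log2(FPKM+1).
- Differential expression: a self-contained negative-binomial Wald test
  (median-of-ratios size factors, method-of-moments dispersion, BH
  adjustment); DE means padj < 0.05 and fold change > 1.5.
- Dispersion comparison: Welch *t*-test of log coefficients of variation,
  candidate-gene vs other transcripts.

**Reverse ecology and function** (`reverse_ecology`, `functional_overlap`)

- Candidate-gene transcripts (CGTs): a homology hit with e-value < 1e−3,
  identity > 50% and alignment covering > 50% of the reference gene.
- Over-representation of CGTs among HD and direction-specific DE
  transcripts: upper-tail hypergeometric tests with Bonferroni correction,
  plus input/output percentage tables.
- Deepest non-overlapping GO term assignment on a GO DAG (depth = longest
  path from the namespace root) and pooled two-proportion z-tests comparing
  shared-GO-term proportions against shared-transcript proportions between
  the HD and DE CGT subsets.

**Associations** (`association_stats`)

- Haversine great-circle distances; one-sided Mantel permutation tests
  between geographic, genetic (*F*_ST) and expression (1 − *r*) distance
  matrices; Pearson correlations of Ed against π within and across
  populations; Wilcoxon signed-rank north-vs-south comparisons of π and Ed
  paired per transcript.

**Synthetic data** (`synthetic_data`) generates every input the pipeline
consumes — Balding–Nichols group divergence, negative-binomial counts with
planted group effects, a planted CGT subset enriched among DE transcripts,
homology hits, a toy GO DAG, coordinates — with known ground truth, so every
stage is testable without downloads.

## Worked example

```python
from popxome import SimConfig, simulate_all
from popxome import genotype_stats as gs, expression_stats as es
from popxome import divergence as dv, reverse_ecology as re_

cfg = SimConfig(n_transcripts=1000, seed=42)
data = simulate_all(cfg)

fst = gs.pairwise_fst(data.genotypes, data.popmap, level="group")
print("group F_ST:", round(fst.values[0, 1], 3))

kept, _ = es.filter_expression(data.expression, data.popmap)
calls = dv.de_test(kept.counts, data.popmap)
print("DE transcripts:", int(calls["is_de"].sum()), "of", len(calls), "tested")

cgt = re_.classify_cgt(data.hits, data.truth.transcript_ids)
dapc = dv.dapc_loadings(data.genotypes, data.popmap)
hd = dv.hd_transcripts(dapc)
table = re_.enrichment_analysis(cgt, calls, hd,
                                dapc_universe=list(dict.fromkeys(dapc["transcript"])))
print(table[["analysis", "input_pct", "output_pct", "diff_pct", "p_bonferroni"]]
      .to_string(index=False))
```

prints

```
group F_ST: 0.496
DE transcripts: 198 of 997 tested
   analysis  input_pct  output_pct  diff_pct  p_bonferroni
       DAPC       14.9        16.6       1.7  2.797171e-01
  DE Nor up       15.0        37.5      22.5  7.588366e-09
  DE Sou up       15.0        37.2      22.2  8.361539e-08
DE Nor down       15.0        37.2      22.2  8.361539e-08
DE Sou down       15.0        37.5      22.5  7.588366e-09
```

The realized group *F*_ST matches the simulation target (0.5). Of the 997
transcripts surviving the expression filter, 198 are called differentially
expressed — predominantly the planted ones. The enrichment table reads like
a reverse-ecology report: candidate-gene transcripts make up ~15% of each
analysis universe (`input_pct`) but ~37% of the DE output sets
(`output_pct`), a strongly significant over-representation (Bonferroni
p ≈ 1e−8) because the generator planted CGTs with four-fold odds of
carrying a group effect; the DAPC (HD) row shows no such enrichment, as
nothing ties the planted CGTs to sequence divergence. In a two-group
contrast "up in the north" and "down in the south" are the same transcript
set, so those rows mirror each other.

The same stages are exposed as a CLI for file-based pipelines:

```sh
popxome simulate --out sim --seed 4
popxome geno fst sim/snps.vcf --popmap sim/popmap.tsv --level group --out fst.tsv
popxome div de sim/counts.tsv --popmap sim/popmap.tsv --out de.tsv
```

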