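# Methods

This note documents the statistical procedures, the synthetic-data model,
the defaults and the design decisions behind `popxome`.

## Study design assumed by the pipeline

Two groups of populations sampled along an environmental gradient (labelled
"north" and "south"), each group containing one or more populations, each
population a set of individuals with both genotype calls (transcript-mapped
SNPs) and expression measurements (raw counts and FPKM). All group
contrasts in the package are two-group contrasts; the DAPC and DE stages
require exactly two groups.

## Sequence statistics

**SNP filter.** Biallelic sites only; missing fraction ≤ 0.5; mean read
depth over non-missing calls ≥ 6 (skipped with a warning when the VCF
carries no DP field); minor allele frequency ≥ 0.02 computed over
non-missing alleles; quality strictly greater than 10 (a site at exactly 10
is removed). The filter is applied in that order, so the MAF reflects
surviving calls only.

**Nucleotide diversity.** Per variant site and population,
π_site = 2·c_ref·c_alt / (m(m−1)) with m the number of called alleles —
the expected pairwise allelic difference. The per-unigene value is the
arithmetic mean over that unigene's *variant* sites. Invariant-site counts
are unavailable for transcriptome-mapped SNP panels, so this is a
per-variant-site π, not a per-bp π; it is comparable across populations on
the same panel but not across studies. Populations with fewer than two
called alleles at every site of a transcript yield no record.

**Weir–Cockerham F_ST.** The 1984 variance-component estimator: per-site
components a (between units), b (between individuals within units), c
(within individuals), combined over sites as Σa / Σ(a+b+c). Per-site
components may be negative and the multi-locus value may be slightly
negative at no differentiation; values are reported as computed (capped at
1). At group level each group is pooled into a single unit. Sites where
fewer than two units have called genotypes are skipped. Note the estimator
is not exactly zero for duplicated samples — its bias correction subtracts
an expected within-unit term — so "no differentiation" manifests as a value
near zero, not identically zero.

**Genotype PCA.** Individuals × SNPs alt-dosage matrix; missing entries
imputed with the SNP mean; columns centered and scaled by √(2p̂(1−p̂));
eigendecomposition of the individual covariance. Components are ordered by
eigenvalue and signed so that the largest-magnitude coordinate of each
component is positive (a deterministic convention; PCA signs are otherwise
arbitrary).

**DAPC loadings.** PCA of the centered (unscaled) dosage matrix retaining
the smallest number of components whose cumulative explained variance
exceeds `var_retained` (default 0.99); a linear discriminant between the
two groups in PC space using the pooled within-group covariance with a
ridge of 1e−6 (the pooled covariance is singular whenever retained PCs
approach the sample count); per-SNP loadings are the squared entries of the
discriminant axis back-projected through the PCA rotation, normalized to
sum to one. Because the PCA rotation is orthonormal and the within-group
covariance acts inside the data span, back-projecting the PC-space solution
equals a ridge-regularized discriminant solve on the raw dosage matrix when
all non-zero components are retained (this identity is exercised in the
tests against a direct solve). HD SNPs are the top ⌈0.1·n⌉ loadings, ties
broken by SNP ID; an HD transcript is any transcript containing an HD SNP.
Cross-validated selection of the retained PCs is out of scope.

## Expression statistics

**Filter.** A transcript is removed if, in any population, its mean FPKM is
below 4 or its standard deviation (ddof=1) exceeds its mean. The rule is
deliberately per-population ("in each population" distributing over both
criteria); a `scope="global"` variant instead compares the SD over all
libraries against each population's mean, for users who prefer that
reading. Populations with a single library have no SD; that criterion is
skipped for them with a warning. The filter is idempotent.

**Ep and Ed.** Ep = ΣEi/n (mean FPKM over a population's individuals);
Ed = Σ|Ei − Ep| / ((n−1)·Ep). Ed is exactly scale-invariant and zero for
constant expression; it is undefined (flagged missing, excluded from
correlations) when Ep = 0 or n < 2.

**Similarity and PCA.** "Normalized FPKM" is log2(FPKM+1) throughout
(pseudocount 1). Population similarity is the mean Pearson r over all
cross-population individual pairs (`mode="pairwise"`); correlating the two
populations' mean log-expression vectors is available as
`mode="ep-vector"`. Expression PCA centers transcripts but does not scale
them.

**Dispersion comparison.** The dispersion coefficient of a transcript is
its coefficient of variation (SD/mean) of FPKM over all individuals — CV is
the natural reading of a dimensionless "dispersion" on FPKM, and the test
operates on log CVs. Only transcripts expressed (FPKM > 0) in more than
half the samples enter. Welch's unequal-variance t-test is used rather than
the pooled-variance form: the candidate and background sets differ greatly
in size, and Welch is the safer default (recorded in the result metadata as
`df`).

## Differential expression

A self-contained negative-binomial Wald test in the DESeq2 mould,
deliberately without dispersion or fold-change shrinkage — the pipeline's
claims concern the procedure (NB model, size-factor normalization, Wald
test, BH adjustment, thresholds), not numerical identity with any
particular implementation. Steps:

1. Size factors by median-of-ratios against a geometric-mean reference
   restricted to transcripts with no zero count.
2. Per-transcript dispersion by method of moments,
   α = (s²_within − m̄)/m̄², floored at 1e−8, where s²_within is the
   pooled *within-group* variance of normalized counts — using the total
   variance would fold the group effect into the dispersion and destroy
   power on strongly differential transcripts.
3. log2FC = log2((m_S + 0.5)/(m_N + 0.5)) on normalized group means; its
   standard error from the NB variance model Var(q) = m/s_j + αm² via the
   delta method; two-sided normal p-values; Benjamini–Hochberg adjustment.
4. DE ⇔ padj < 0.05 and |log2FC| > log2(1.5); direction labels ("south-up"
   / "north-up") are defined only for DE calls. All-zero transcripts are
   excluded and listed in the result's `excluded` attribute.

On planted-signal simulations the call set matches an external DESeq2-style
reference (pydeseq2) with Jaccard ≥ 0.9 and log2FC correlation > 0.99
(tested); on null simulations the false-positive fraction at padj < 0.05 is
controlled.

## Candidate genes and over-representation

A transcript is a CGT when any homology hit passes e-value < 1e−3,
identity > 50 and coverage > 0.5, all strict. Coverage is alignment length
over the *subject* (reference gene) length — "the target gene covered more
than half" is the intended reading — with `coverage_basis="query"`
available for the alternative. The best hit is the passing hit with the
smallest e-value (ties: highest identity, then subject ID).

Over-representation is tested with the upper-tail hypergeometric
distribution: p = P(X ≥ k) for k CGTs among n output transcripts drawn from
a universe of N transcripts containing K CGTs; Bonferroni multiplies by the
number of tests in the run (five in the standard report: DAPC plus four
direction-specific DE categories; in a two-group contrast north-up equals
south-down, so those rows share counts). Only over-representation is
tested; under-represented rows simply show p near 1. Report percentages are
rounded half-up to one decimal; raw counts are kept unrounded.

## GO assignment and functional overlap

The GO DAG is a child→parent edge list with a namespace per term (BP, MF,
CC), validated to be acyclic with one root per namespace. Depth is the
*longest* path to the root — the convention under which "deepest" means
most specific. Per transcript and namespace the deepest annotated term is
chosen (ties: fewest descendants, then lexicographic ID). Non-overlap is
then enforced set-wide: any chosen term that is a strict ancestor of
another chosen term is replaced by the transcript's deepest annotated
alternative that is not an ancestor of any other chosen term, when such an
alternative exists; the pass runs in sorted transcript order and repeats to
a fixed point (bounded at ten sweeps). When no valid alternative exists the
original term is kept — the procedure prefers an informative assignment
over dropping the transcript.

Overlap between the HD and DE CGT sets is summarized per namespace:
shared transcripts (intersection), shared assigned terms, and directional
percentages (divided by the HD side and by the DE side). A pooled
two-proportion z-test (no continuity correction, two-sided) compares the
shared-term proportion against the shared-transcript proportion in each
direction; a term excess indicates functional convergence of distinct
transcript sets.

## Associations

Geographic distances are haversine great circles with Earth radius
6371.0088 km. Mantel tests correlate upper triangles and permute the second
matrix's rows and columns jointly; the test is one-sided for positive
association (the isolation-by-distance question), with
p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1) and a default of 1,000
permutations; similarity matrices are converted to distances as 1 − r
first. Ed–π correlations are Pearson, per population over shared
transcripts ("within") or over population means ("across"). The
north–south comparison is a Wilcoxon signed-rank test paired per transcript
on group-mean values (transcripts are the only pairing unit with enough
replication), zero differences dropped, exact null distribution for small
tie-free samples and the tie-corrected normal approximation otherwise.

## Synthetic-data model

The generator emulates the assumed study design end to end with one global
seed; every component draws from a fixed substream, so outputs are
byte-identical across runs.

- **Genotypes.** Ancestral frequency p ~ U(0.05, 0.95) per SNP; each group
  draws its frequency from Beta(p(1−F)/F, (1−p)(1−F)/F) with F =
  `fst_target` (Balding–Nichols; F = 0 keeps the ancestral frequency);
  populations within a group share the group frequency; genotypes are
  Binomial(2, freq). SNP counts per transcript are Poisson. A
  `frac_divergent` knob restricts divergence to a transcript subset (1.0 by
  default, i.e. genome-wide divergence). The realized group-level
  Weir–Cockerham F_ST tracks `fst_target` closely (tested at 0, 0.1, 0.3,
  0.5).
- **Expression.** Baseline means log-normal (log-mean ln 150, log-SD 1.2 —
  a typical bulk RNA-seq spread with most transcripts comfortably above the
  FPKM filter floor); planted DE transcripts get a ±`lfc_scale` log2 shift
  in the south group; counts are NB with dispersion `nb_dispersion` and
  log-normal library-size factors (σ = 0.15, redrawn if below a tenth of
  the median); FPKM is computed from the counts, simulated lengths and
  per-library totals, so the matrices are mutually consistent.
- **Annotations.** Planted CGTs get a homology hit passing all three
  criteria; other transcripts get no hit or a hit failing exactly one
  criterion, so classifier recall and precision are 1 by construction. DE
  planting uses Gumbel top-k weighted sampling giving CGTs
  `cgt_de_enrichment`-fold odds. The GO DAG is a fixed ~60-term,
  three-namespace structure (depth ≤ 5, with diamonds); transcripts
  annotate to 1–5 leaves. Coordinates are four populations on a meridian.

**Defaults** (one simulated study): 4 populations in 2 groups, 12
individuals per population (mirroring a ~50-individual, four-population
sampling design), 2,000 transcripts with Poisson-8 SNPs each (~16k SNPs),
`fst_target` 0.5, `lfc_scale` 2, `nb_dispersion` 0.05, `frac_cgt` 0.15,
`frac_de` 0.2, `cgt_de_enrichment` 4. These sizes keep a full pipeline pass
in seconds while leaving all stages well-powered.

**What the generator does not emulate:** linkage disequilibrium within
transcripts, read-level noise (FASTQ), isoform structure, batch effects,
missing genotypes and depth variation (the SNP filter's missingness and
depth rules are exercised on hand-built fixtures instead), selection
models, and any coupling between sequence divergence and expression
divergence beyond the planted CGT–DE association. Passing tests therefore
demonstrate correctness of the procedures under the stated model, not
robustness to those real-data complications.

## Known limitations

- The DE stage is unshrunk; on very small samples or very low counts its
  fold changes are noisier than shrinkage-based estimators.
- Under the Balding–Nichols model at high F the Beta distribution is
  U-shaped: a substantial fraction of "divergent" SNPs draw nearly equal
  group frequencies and are statistically indistinguishable from
  non-divergent ones at realistic sample sizes. The fixed top-decile
  loading cut then necessarily includes null SNPs, which scatter across
  transcripts; transcript-level HD precision against the planted subset is
  therefore intrinsically modest (~0.3 at the default design, vs ~0.94 for
  an oracle ranking on the true frequency differences). This is a property
  of the model and threshold rule, not of the loading estimator.
- Per-variant-site π is panel-dependent; comparisons are only meaningful
  within one filtered SNP panel.
- The deepest-non-overlapping GO assignment is a greedy procedure with
  repair; it attains the brute-force optimum on small fixtures (tested) but
  carries no global optimality guarantee.
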