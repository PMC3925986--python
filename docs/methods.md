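# Methods

This note documents the statistical procedures, the defaults and the design
choices behind `embryostage`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Study design the package assumes

Samples are pooled embryos (several embryos per library) collected along an
ordered developmental stage series: oocyte, 1-cell, 2-cell, 4-cell, 8-cell,
morula, and a blastocyst split mechanically into a pure trophectoderm half
(`TE`) and a half containing the inner cell mass plus residual trophectoderm
(`ICMTE`).  There are no biological replicates within a comparison group —
at most a second collection set — so all tests operate on pooled counts.
The stage order is configuration, not code: a mouse series (ZGA at 2-cell),
a pig series (4-cell) and an SCNT series (8-cell) run through identical
machinery.

## Normalization and quantification

**TMM factors.** Library composition shifts (e.g. bulk maternal transcript
degradation) bias naive per-million scaling, so per-sample factors are
computed as a trimmed mean of M-values.  The reference library is the one
whose upper-quartile nonzero counts-per-million is closest to the mean upper
quartile.  For each library, over genes nonzero in both it and the
reference, M = log2 ratio of count proportions and A = mean log2 abundance;
the extreme 30% of M and 5% of A (per tail) are discarded — standard trims
for this statistic — and the factor is 2 to the precision-weighted mean of
the surviving M, with delta-method weights 1/[(n−k)/(nk) + (n_r−k_r)/(n_r
k_r)].  Factors are rescaled to geometric mean 1.  Trimming tie-break is by
original gene position (stable), making the computation exactly
reproducible.  If fewer than 10 genes survive trimming the factor falls back
to 1 with a warning.  Note the precision weights depend on absolute counts,
so factors are only *approximately* invariant to rescaling a single library;
proportion-identical libraries (the doubled-column case) give exactly 1.

**RPKM.** `1e9 × count / (effective library size × exonic length in bp)`,
where the effective library size is the raw column sum times the TMM factor
(a flag restores plain RPKM).  Log transforms use a pseudocount of 1 (so
zero maps to zero) in base 10 by default; base 2 is available because both
conventions are common in replicate-correlation reporting.

## Differential expression without replicates

Two pooled libraries cannot support per-gene dispersion estimation.  Under a
random-sampling (Poisson) model, conditioning on the total t = k1 + k2
removes the nuisance scale: under the null of equal proportions,
k1 ~ Binomial(t, n1/(n1+n2)) with n the effective library sizes.  The
two-sided p-value doubles the smaller tail, inclusive of the observed count,
capped at 1 — the simplest defensible two-sided convention for a discrete
test.  Totals above 10,000 switch to a normal approximation with continuity
correction (the exact and approximate branches agree to a few percent at the
boundary).  t = 0 gives p = 1 by convention.

Multiple testing uses the Benjamini–Hochberg step-up rule,
q_(i) = min_{j≥i} m·p_(j)/j, implemented once and shared by the enrichment
module.  A gene is significant iff q < alpha (default 0.05) **and** its fold
change is strictly greater than 2 (or below 1/2).  Fold changes are ratios
of normalized pooled proportions with 0.5 added to both pooled counts to
avoid division by zero.  This is a deliberate reimplementation of the
replicate-free two-library test family; an MA-plot z-test variant
(`ma_ztest_pvalues`) is included for comparison and ranks genes nearly
identically.

The conditional test is exact only under sampling noise.  With truly
independent overdispersed libraries it is anticonservative — a fundamental
limitation of replicate-free designs, not of this implementation; see the
noise-model discussion below.

## Maternal/zygotic classification and ZGA detection

- **Maternal deposit**: mean oocyte RPKM > 3, strict.  By construction this
  captures *every* oocyte-expressed transcript, constitutive housekeeping
  genes included; that is the intended semantics of a deposit rule based on
  oocyte expression alone.
- **Regulated genes per transition**: the DE rule applied to each
  consecutive stage pair, counting significant up- and down-calls
  separately (replicates pooled within stages).
- **ZGA stage**: the downstream stage of the transition maximizing total
  regulated genes (up + down, since activation coincides with bulk maternal
  degradation); ties break to the earlier transition and are logged.  An
  up-only mode is available.
- **Zygotic activation** ("transcription trend" formalized): mean oocyte
  RPKM ≤ 3, significantly up-regulated at some transition up to and
  including the ZGA transition, and mean RPKM > 3 at that transition's
  downstream stage.  Persistence through later stages is *not* required.
  The oocyte threshold shared by both rules makes maternal and zygotic sets
  disjoint by construction.

## ICM inference from split blastocysts

A pure ICM sample cannot be dissected; instead ICMTE is compared against TE
with the standard DE rule plus a floor of RPKM > 3 in the ICMTE sample (the
sample the gene is called specific in; the floor can be switched to the TE
sample or both).  The caller is the plain subtraction test — no
deconvolution of the mixing fraction f is attempted; the latent-mixture
view (ICMTE = f·ICM + (1−f)·TE) exists only in the simulator and in
evaluation.  As f shrinks, the observable ICMTE/TE fold of a true ICM gene
is f·φ + (1−f) for a latent fold φ, which drops below the 2-fold gate near
f ≈ 1/7 for φ = 8 — the measured sensitivity collapse at small f is the
method's real detection boundary, not an artifact.

Morula co-expression lists are plain intersections: morula expressed (mean
RPKM > 3) with the ICM-specific list, and with the TE expressed list
(TE RPKM > 3).

## Cross-species comparison

Gene identifiers are opaque strings; species meet only through a one-to-one
ortholog table (ids mapped in more than one pair disqualify all their
pairs).  Overlap reports give pairwise/three-way intersections, the shared
percentage of each set, and Jaccard indices; percentages of empty sets are
flagged undefined, never reported as 0.  Transcriptome similarity uses three
coefficients — Pearson, Spearman (average-rank ties) and Kendall tau-b —
over log10(RPKM+1) of shared genes; which triple the original analyses used
is undocumented, so the most common triple is implemented and labelled
explicitly.  Sample clustering is UPGMA (average linkage) on Euclidean
distances, computed on log-transformed normalized expression by default
(raw counts are an option for literal reproduction); samples are sorted
lexicographically first so tie-breaking is deterministic, and trees export
to Newick with branch lengths equal to height differences.

## Marker-hub co-expression networks

Marker panels for the three lineage layers (ICM segregation, primitive
endoderm differentiation, TE commitment) default to the classic pluripotency
and commitment factor lists, restricted to genes with one-to-one pig/mouse
orthologs (Klf2, Rex1, Gata4, Mixl1, Sox7 and Pace4 drop out).  Profiles are
stage means of log expression over the whole series (at least 4 stages).
Candidate targets are non-marker genes with RPKM > 3 at one or more stages
(an explicit floor; whether the original procedure used one is
undocumented).  An edge is added when |Pearson r| > 0.9, strictly, weighted
by |r|.

Singleton pruning: a marker whose target set shares, with every other
marker, less than 5% of targets — fraction measured against the *smaller* of
the two target sets, the most permissive symmetric convention; a union
denominator is available — is removed together with targets linked to no
surviving marker.  Because both denominators are symmetric, surviving
markers justify each other and the operation is idempotent.

## Enrichment

Over-representation is an upper-tail hypergeometric test per category with
BH correction.  The length-aware variant replaces the uniform null by
Monte-Carlo resampling: selection weights come from an isotonic (monotone)
regression of list membership on log gene length, and each of n_resample
(default 10,000) draws samples |list| genes without replacement with those
weights; p = (1 + #{k* ≥ k})/(1 + n_resample), never zero by the add-one
correction.  Direct weighted resampling is used instead of a Wallenius
noncentral-hypergeometric approximation: simpler, exact in the limit, easy
to test (uniform weights provably reduce to the hypergeometric null).
Category annotations are a flat gene→category table; no ontology topology
or term propagation.

## The synthetic study generator

`generate(GeneratorConfig(...))` emulates the full design with exact planted
truth.  Gene classes partition the panel: decaying maternal deposit (20%),
stable deposit/housekeeping (35%), zygotic (15%), ICM program (3%), TE
program (3%), low noise (rest).  Per condition: maternal transcripts decay
exponentially (retention 0.15 per stage) from the ZGA stage; zygotic genes
jump 8-fold at ZGA from a near-silent baseline (0.8–2.4 RPKM); lineage
genes are low through cleavage, half switch on in the morula, and the
blastocyst columns follow latent profiles with the ICM-side 8-fold above
the TE-side; the ICMTE column is literally f·ICM + (1−f)·TE (f default
0.5).  A second condition keeps a configurable share of the first's
maternal deposit and zygotic program (defaults mirror the reported
in-vivo/SCNT and pig/mouse sharing levels); demoted deposit genes become
zygotic-only there, and orthology is an identity-renaming map over 90% of
gene indices.

Two properties require care:

- **Absolute scale.**  RPKM is compositional — only expression *ratios* are
  free; the absolute level is fixed by the whole transcriptome.  The
  generator therefore budgets total expression mass (Σ RPKM×length = 1e9 at
  the reference oocyte stage) and lets the stable class absorb the
  remainder, so planted levels are realized RPKM almost exactly; exact
  expected RPKM per gene, stage and condition is computed and stored in the
  truth table, and all truth sets are derived by applying the package's own
  thresholds to those expected values.  Class levels are drawn away from the
  decision thresholds (noise ≤ 2.4, stable ≥ 5, decaying deposit ≥ 8 RPKM;
  lengths ≥ 600 bp) so that count rounding cannot flip a label in the
  noiseless regime — a ground-truth generator should not plant ambiguous
  genes.
- **Noise model.**  Overdispersion enters as a per-gene multiplicative
  Gamma(1/d, d) effect (dispersion d default 0.1) shared across all samples
  of a condition, plus per-sample Poisson sampling.  Marginally every count
  is negative-binomial with dispersion d around its length- and
  library-scaled mean; crucially, *between-sample* ratios remain
  conditionally binomial, the regime the replicate-free test assumes, which
  is the appropriate model when libraries are pools of many embryos drawn
  from a common biological program.  This is a modelling choice: with fully
  independent per-library negative-binomial noise, no replicate-free test
  can control the false discovery rate, and the benchmarks would measure
  that impossibility rather than the implementation.  Dispersion 0 yields
  deterministic rounded expected counts for exact tests.  Library sizes are
  log-normal (median 3e6, sigma 0.2 on the log scale); gene lengths
  log-normal (median 1.5 kb, sigma 0.5); 2 replicates per stage.

What the generator does **not** emulate: mapping/counting artifacts,
transcript-level variation and isoform switching, per-embryo heterogeneity
within pools, batch effects between collection sets, sequence-driven biases
(GC, 3' coverage), or dropout patterns of true single-cell data.  Passing
recovery benchmarks therefore demonstrates correctness of the pipeline's
logic under its stated sampling model, not robustness to every artifact of
real libraries.

## Benchmarks (what `scripts/acceptance.py` measures)

All quantities are recomputed from scratch at fixed problem sizes chosen to
finish in minutes on one CPU: 10,000 null genes at depth 1e6 for the type-I
rate; 5,000 genes with 200 planted 8-fold changes for DE recall/FDR; 100
seeded 2,000-gene series per condition for ZGA detection; 3,000-gene series
for classification recovery (noiseless and dispersion 0.1); 5,000 genes with
150 planted ICM genes for the mixture test; 10,000 genes at a planted 80%
maternal share for the overlap statistic; 30 markers × 20 targets + 200
noise genes for network recovery.  The classification and single-condition
benchmarks use a one-condition configuration so the oocyte mass calibration
is exact; multi-condition runs shift composition (that is realistic, and the
truth tables account for it, but exact set equality is only claimed for the
calibrated reference condition).

## Known limitations

- The conditional binomial test inherits all caveats of replicate-free DE:
  it tests sampling equality of two libraries, not biological equality of
  two conditions.
- The headline gene counts and overlap percentages of any specific study
  depend on its sequencing depth, annotation version and ortholog build;
  this package reproduces the *procedures* and validates them on synthetic
  data with known truth, not those dataset-bound numbers.
- Kendall tau-b is computed per sample pair via pairwise statistics
  (O(S²) pairs); for very large sample counts Spearman is the cheaper rank
  option.
- GraphML export carries node groups and edge weights but no layout;
  rendering is out of scope.
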