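# Methods

This note records the models and procedures `sigstrat` implements, the
parameter choices that matter, what the synthetic cohort generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## Variant filtering

A call is removed when any of the following holds: variant allele
fraction < `min_vaf` (default 0.05); depth < `min_depth` (default 100)
**or** depth < `median_depth_fraction` (default 0.10) × the median depth
of that sample's variants; call quality < `min_phred_quality` (default
100); strand-bias Phred score > `max_strand_bias_phred` (default 60); a
homopolymer run of ≥ `homopolymer_min_run` (default 6) identical bases
overlapping the ±`homopolymer_window` (default 5) bases around the
variant; an upstream germline or common-SNP annotation flag; or a
variant class outside the allowed set (all exonic consequences plus
splice; intronic excluded).

Interpretation choices, all config-exposed:

* The two depth clauses are treated as independent removal criteria
  (OR), since either alone marks an unreliable call; `depth_rule="and"`
  gives the conjunction reading.
* The median is the median **read depth** over the sample's variants
  (not median VAF), computed before any removal so verdicts are
  order-invariant.
* The 5% threshold applies to the variant allele fraction of the call
  (the quantity a tumour-only panel pipeline thresholds), not a
  population allele frequency; population-level filtering arrives as
  pre-computed germline/SNP flags on the input records.
* The strand-bias score is PS = −10·log₁₀ p with p from the two-sided
  Fisher exact test of [[ref_fwd, ref_rev], [alt_fwd, alt_rev]].  The
  sign makes PS a positive badness score that can exceed a removal
  threshold of 60 (p < 10⁻⁶); PS is capped at 1000 when p underflows,
  and an all-zero table returns p = 1 with a warning.  Sidedness is not
  dictated by the workflow being reproduced; two-sided is the neutral
  choice.
* "Homopolymer region" is operationalized as a mononucleotide run of at
  least six bases overlapping the ±5 bp neighbourhood of the variant, a
  reading suited to flow-based sequencing error modes.

Every rule is always evaluated, so each verdict lists all violated
rules, and relaxing any single threshold can only turn failures into
passes (a tested monotonicity property).

## 96-motif spectra

Each SNV is assigned one of 96 motifs: the substitution reported on the
pyrimidine strand (C>A, C>G, C>T, T>A, T>C, T>G) plus its 5′ and 3′
flanking bases, read from the stored 41-base reference context.
Purine-reference calls are reverse-complemented together with their
flanks.  The canonical row order is substitution-major, then 5′ flank
A/C/G/T, then 3′ flank A/C/G/T — the ordering of COSMIC SBS matrices, so
reference files align row-wise.  Non-SNVs and contexts truncated by an
`N` flank are excluded from spectra (multi-base events keep a stable
first-changed-base coordinate for kataegis ordering).

## De novo signature extraction

The motif-by-sample count matrix V (96 × n) is factorized V ≈ W·H,
W, H ≥ 0, by multiplicative updates minimizing the generalized
Kullback–Leibler divergence Σ v log(v/ŵ) − v + ŵ — the objective
appropriate for count data.  Details:

* Initialization: W ~ U(0,1] i.i.d.; H ~ U(0,1] scaled by mean(V).
  This makes the fit exactly scale-covariant (scaling V by c scales H by
  c and leaves W unchanged) and deterministic per seed.
* Stopping: relative objective change ≤ tol (default 10⁻⁶, checked
  every 10 iterations) or an iteration cap (default 500; 300 inside
  rank selection with tol 10⁻⁵).  The KL objective is non-increasing
  under these updates, which a test asserts on every instance.
* After convergence W's columns are normalized to sum 1 with the inverse
  scaling absorbed into H, so W columns are probability distributions
  over motifs and H carries the mutation counts.
* Goodness of fit is reported as RSS = ‖V − WH‖²_F and explained
  variance = 100·(1 − RSS/‖V‖²_F), clipped to [0, 100].  (The fit
  criterion is KL; RSS/EV are the conventional reporting statistics.)

**Rank selection.**  For each rank in the candidate range (default
1–4), `n_restarts` factorizations are run (default 500; the test suite
and acceptance experiment use 50, which already yields stable consensus
at these problem sizes).  Each restart assigns every sample to its
maximal-exposure signature; the n × n consensus matrix averages these
co-assignments over restarts, and the cophenetic coefficient is the
Pearson correlation between the consensus dissimilarities (1 −
consensus) and the cophenetic distances of their average-linkage
hierarchical clustering.  Rank 1 is excluded (its consensus is all-ones
by construction, reported as NaN); a consensus that is identical in
every restart short-circuits to a coefficient of 1.

The selected rank is, by default, the **largest rank attaining the
maximal cophenetic coefficient** among ranks whose coefficient exceeds
the stability threshold (default 0.95), with a 10⁻⁶ tie tolerance
resolved towards the larger rank.  The rationale: on data genuinely
generated from k processes, ranks below k can also cluster samples
reproducibly (merging two processes the same way in every restart), so
the coefficient typically sits near 1 for 2..k and falls — slightly but
consistently — above k, where restarts disagree about how to split a
cluster.  A pure "largest rank above 0.95" rule (available as
`rank_rule="largest_stable"`) over-selects whenever the drop above k
stays within the threshold, which is exactly the regime observed on the
synthetic three-signature cohorts.  If no rank ≥ 2 is stable the
selection falls back to a single signature with a warning.

Extracted signatures are mapped onto a reference set by greedy
one-to-one cosine matching; matches below cosine 0.6 (configurable)
report as unmatched.

## Supervised exposure refitting

A 96-vector spectrum s is decomposed over a reference matrix R by
non-negative least squares min ‖s − R·e‖₂, e ≥ 0 (deterministic
active-set solver).  Exposures below 1% of the total exposure are
pruned to zero and the fit re-solved on the surviving support —
a guard against low-level signature bleed.  Subgroup profiles fit the
**pooled** (summed) spectrum of the subgroup's samples; per-sample
profiles are returned alongside for dispersion reporting.  Fitting on
raw counts keeps exposures in mutation units; fractions normalize to 1.

## Kataegis

All mutations (cohort-pooled by default, per-sample on request) are
ordered by chromosome and position; intermutation distance is the bp
gap to the previous mutation on the same chromosome, 0 for ties, and
undefined for the first.  The per-chromosome series x = log₁₀(d + 1) is
segmented by exact penalized least squares — dynamic programming over
Σ_segments [SSE(segment) + penalty] — which is the "constant fitting"
notion of finding regions of constant intermutation distance.  A
segment covering distances d_a..d_b spans the mutations a−1..b, so its
mutation count is its distance count plus one.  A segment is a kataegis
focus iff it has ≥ 6 mutations and mean raw distance ≤ 1000 bp.

The default per-segment penalty is 1.0 (in squared-log₁₀ units).  At
that penalty an isolated six-point cluster at ~500 bp spacing against a
background at ≥ 10 kb scale is always split out (the SSE gain at the
two boundaries is an order of magnitude above the 2-unit penalty cost),
while background fluctuations are not worth a boundary; the
segmentation is verified against exhaustive search on short series.
Detection is specified for cohort densities below about one mutation
per 10 kb; pooling a much denser cohort shrinks background gaps towards
the 1 kb rule boundary and, separately, recurrent hotspot positions
shared across samples create zero-distance runs that satisfy the
predicate literally.  Both effects are properties of pooled calling on
dense data, not of the segmentation; per-sample mode avoids them.

## APOBEC enrichment

For each sample, mutated cytosines are counted on the
pyrimidine-normalized strand (guanine-reference records are
reverse-complemented), by default restricted to C>T and C>G — the
deamination outcomes; a config flag widens to all mutated cytosines.
`mut_tcw` counts those whose immediate context is t-C-w (w = A or T).
Background c and tcw are tallied over the full 41-base window around
each counted mutation (the 20 flanking bases each side plus the mutated
base itself); windows of nearby mutations may overlap and are counted
per occurrence, matching the per-mutation framing of the enrichment
formula

    E = (mut_tcw × background_c) / (mut_c × background_tcw).

A sample is APOBEC-positive iff E > 2 (strict).  E is undefined when
`mut_c` or `background_tcw` is zero; such samples are reported
not-positive with a warning.  No significance test accompanies the
threshold — only the threshold rule is implemented.

## Genomic instability

TML = somatic mutation count × 10⁶ / covered exonic bases, classified
high at ≥ 20 mutations/Mb.  "Sufficiently covered" is defined as bases
at or above the filter's minimum depth (100×); the denominator arrives
as panel metadata, since base-level coverage is not reconstructable
from a variant table.  By default all post-filter somatic variants are
counted; a flag restricts to non-synonymous.

MSI uses the five-locus panel BAT25, BAT26, D2S123, D5S346, D17S250:
MSI-H at ≥ 3 unstable loci, MSS at 0.  One or two unstable loci have no
defined call in the two-class rule, so they are labelled
`indeterminate` rather than forced into MSS; downstream association
tests treat indeterminate as non-MSI-H.

## Cohort statistics

Samples are labelled by the two designated driver genes (defaults
*ARID1A*, *PIK3CA*): first-only, second-only, "Double hit" (both) or
"Undetermined" (neither).  A qualifying mutation is any non-silent
variant class; silent calls never toggle membership.  Pairwise
co-occurrence / mutual exclusivity screens all genes mutated in at
least `min_mutated_samples` (default 5) samples with the two-sided
Fisher exact test on the 2 × 2 presence table; direction requires
p < α (default 0.05, unadjusted — the convention of somatic-interaction
screens; Benjamini–Hochberg is available but off by default) and an
odds ratio above or below 1.  Because the union denominator of a
two-gene co-occurrence percentage is convention-dependent, the
`union_cooccurrence` helper reports |both|, |union| and their ratio
without asserting one convention as truth.  Gene-set tallies report the
fraction of samples with ≥ 1 qualifying mutation in each user-supplied
set (GMT input); the pathway sets themselves are user data, not package
claims.

## The synthetic cohort generator

The generator is the package's ground-truth instrument: every
downstream stage is tested against what the generator knows it planted.
A cohort is drawn on a toy genome of three 10-Mb chromosomes (no
external reference needed).  Per sample:

* A subgroup label is drawn with prevalences 14/55, 10/55, 13/55, 18/55
  (ARID1A-only, PIK3CA-only, Double hit, Undetermined) — the partition
  implied by driver prevalences of 49.1% and 41.8% with 13 doubly
  mutated samples in a 55-sample cohort.
* The background mutation count is negative-binomial with mean 200 and
  dispersion 10.  200 mutations/sample is the regime in which the
  three-signature structure is recoverable by NMF at desk scale;
  dispersion 10 gives the over-Poisson spread of panel counts.
* Each SNV's motif is drawn from the subgroup's mixture of three
  ground-truth signatures (weights 0.8/0.1/0.1 with the dominant
  component shared by the ARID1A and Undetermined subgroups — the
  similarity structure the subgroup analysis expects).  The signatures
  themselves are sparse random draws: 85% of each column's mass on one
  substitution class (C>T, T>C, C>A respectively) spread
  Dirichlet(0.08) over its 16 motifs, the rest Dirichlet(0.05)
  elsewhere; columns are re-drawn until pairwise cosine ≤ 0.3 and until
  at most 10% of each column's C>T/C>G mass lies in tCw motifs.  The
  last constraint keeps baseline samples APOBEC-negative: unconstrained
  sparse draws frequently concentrate in tCw by chance and would fake
  APOBEC positivity cohort-wide.
* A 41-base context is synthesized per variant, consistent with its
  motif, flanks uniform; the emitted strand is randomized to exercise
  pyrimidine normalization.  Contexts are repaired if a homopolymer run
  arises by chance, so homopolymer filter failures are exclusively
  designed events.
* Driver events follow the subgroup: a 3-bp in-frame deletion hotspot
  in the first driver gene (hotspot fraction 0.444) and a missense
  hotspot in the second (0.478), otherwise random non-silent SNVs in
  the gene region.
* One sample in six is APOBEC-enriched: 30% of its C>T/C>G mutations
  are forced into tCw context — enough to push E clearly above 2
  without being degenerate.
* Planted kataegis clusters (default 6/8/10 mutations at 400 bp
  spacing in the first three samples) are placed with uniform ±50%
  jitter on the gap; all other placement is uniform over the genome.
* Read metrics: depth is negative-binomial around 732× (the panel
  coverage regime); VAF ~ U(0.15, 0.6) with binomial strand splits.
  Small designated fractions (2–3% each) of background variants receive
  an engineered defect — low depth, sub-5% VAF, low quality, one-sided
  strands, an injected homopolymer run, or a germline/SNP flag — and
  the generator records, per emitted record, exactly which filter rules
  it expects to fail (re-deriving the strand-bias and median-depth
  verdicts from the drawn values once the sample is complete).
* MSI: the number of unstable loci is drawn with P(≥3) ≈ 0.07,
  emulating the low MSI-H frequency of this tumour type; MSI-H samples
  get a 1.5× mutation-count multiplier so MSI-H and high TML tend to
  co-occur.  Covered exonic bases are ~N(12.5 Mb, 0.5 Mb), which under
  the 200-mutation default yields roughly a quarter of samples at
  TML ≥ 20.

Two named study configurations freeze the conditions of the package's
headline experiments: `CohortSpec.signature_study` (rank-selection /
explained-variance experiment: noise channels, APOBEC and kataegis off,
so spectra reflect the signature model alone) and
`CohortSpec.kataegis_study` (10 samples × ~100 mutations ≈ one mutation
per 30 kb pooled, no driver hotspots, so planted clusters stand against
a clean background).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real genome base composition and
trinucleotide availability (contexts are uniform beyond the motif),
gene models and codon-level consequences (classes are drawn, not
derived), indel/doublet mutational processes, FFPE deamination
artifacts, copy number and purity effects on VAF, correlated
sequencing-error modes, and real COSMIC signature shapes (the bundled
reference set is synthetic, marked `syn`, and is a fixture, not data).
Recovery results on synthetic cohorts demonstrate the correctness of
the implementations under their stated assumptions, not clinical
performance.

## Experiment sizes and numerical choices

* The rank-selection experiment runs 20 master seeds × ranks 1–4 × 50
  restarts on 55-sample, 200-mutation cohorts; the acceptance script
  runs one such cohort.  These sizes give stable consensus matrices
  while keeping the full suite at desk scale (minutes on one CPU).
* Fisher p-values in tests are verified against exhaustive
  hypergeometric enumeration over every 2×2 table with all margins
  ≤ 30; the segmentation is verified against exhaustive partition
  search on series of ≤ 12 points; NNLS is verified on constructed
  exact mixtures to 10⁻⁶.
* Numerical guards: a 10⁻¹² floor inside NMF update denominators and
  logs; signature columns renormalized exactly when within 10⁻³ of unit
  sum on input, else rejected; the strand-bias Phred score capped at
  1000; zero-total exposure vectors return zero fractions rather than
  NaN.
* Degenerate inputs are contracts, not crashes: empty record lists
  produce empty outputs through the filter and kataegis paths;
  all-zero spectra and all-zero sample columns are rejected with named
  errors; an all-zero strand table warns and reports no bias.

## Known limitations

* The cophenetic rank rule is a heuristic; on cohorts whose processes
  are not well separated, ranks 2 and 3 can tie at coefficient 1 and
  the larger-rank tie-break decides.  The per-rank statistics are
  always reported so the decision is auditable.
* Cohort-pooled kataegis calling on dense cohorts or in the presence of
  recurrent hotspots over-calls by construction (see above); gene-level
  annotation of foci is limited to optional interval overlap, as no
  annotation source ships with the package.
* Exposure refitting uses Euclidean NNLS on raw counts; no bootstrap
  confidence intervals or sparsity-driven signature selection beyond
  the 1% pruning are provided.
* VCF support is deliberately a subset (first alternate allele,
  declared INFO/FORMAT keys); MAF-like tables are the native format.
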