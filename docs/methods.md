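# Methods

This note documents the models and procedures implemented in `tedrift`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Transposition–drift model (`tedrift.simulate`)

State per lineage and generation: donor alleles (0–2), counts of
homozygous and heterozygous new-insertion loci, a permanent silencing
flag, and a cumulative excision-footprint count. Loci are unlinked and
carry no genomic position; the model tracks counts only.

Per generation, sub-steps run in a fixed order:

1. **Transposition.** The number of events is Poisson(K · c_active),
   where c_active counts active alleles at the start of the generation:
   donor alleles only under the master-gene variant; donor plus 2 per
   homozygous and 1 per heterozygous new locus under the transposon
   variant. Copies created in generation *t* become active in *t*+1.
   Each event creates one heterozygous locus.
2. **Excision.** Each event independently excises its source allele with
   probability E. The source is drawn uniformly among the active alleles
   still present; excising one allele of a homozygous locus leaves it
   heterozygous, excising a heterozygous or donor allele removes it and
   increments the footprint counter. If every active allele has been
   excised, remaining excisions lapse.
3. **Segregation.** Every heterozygous locus — including loci created in
   this generation, and a heterozygous donor — independently fixes with
   probability 1/4, stays heterozygous with 1/2, or is lost with 1/4.
   Homozygous loci persist.
4. **Silencing check.** If the copy number reaches l, the lineage is
   silenced permanently and concertedly (donor included). The count used
   is configurable: new-insertion alleles only (2·n_hom + n_het, the
   default) or including donor alleles.

Transposition order before segregation means a copy created in
generation *t* has experienced g − t + 1 meioses by generation *g*; at
K = 0.4 and g = 6 this puts the expected per-line heterozygous count
(3.34) below the homozygous count (4.86), both matching the closed-form
split Σ_t 2K(1+K)^(t−1)·2^−(g−t+1) (tested). Observed datasets can show
the opposite ordering when insertions from the parent's reproductive
phase are detected before any meiosis; that census-timing effect is
outside the model.

Two consequences worth noting:

- With E = 0 the expected allele count is conserved through segregation,
  so the master model accumulates linearly (K · donor alleles per
  generation) and the transposon model geometrically (factor 1 + K per
  generation). Both closed forms are Monte-Carlo-tested.
- After silencing the number of insertion *loci* never increases, but the
  *allele* count can still tick up when a heterozygous locus fixes
  (1 allele → 2). Monotonicity tests therefore assert the locus count.

Default scenario: generation 0 is an F2 individual homozygous for the
donor; six generations reach F8. Populations are advanced in lock-step
with vectorised draws from a single seeded generator, so runs are exactly
reproducible given the seed; `simulate_lineage` offers per-lineage
stepping through the same transition kernel.

## Peacock statistic and grid fit (`tedrift.fit`)

The two-sample 2D Kolmogorov–Smirnov statistic maximises the absolute
difference in quadrant probabilities over all four quadrant orientations.
Because zygosity counts are small integers, the supremum over continuous
anchors is attained on the lattice spanned by the union of observed x-
and y-values; the implementation evaluates all four orientations at every
lattice anchor exactly via padded cumulative histograms. The suite checks
it against an independent brute-force oracle that counts quadrant
memberships point by point.

The grid search simulates one pooled population of `reps` lineages per
grid point (pooling maximises the resolution of the simulated CDF), each
grid point on an independent child stream spawned from the master seed so
results do not depend on grid ordering. Ranking uses the raw D statistic;
a permutation p-value (pool and resplit) is available but not used for
ranking. Ties are broken towards parsimony: master variant first, then
smaller K, E, l. The observed sample is assumed to come from
donor-carrying lines.

Identifiability note: at K = 0.4 over six generations, an excision
probability of 0.05 produces ~0.7 excisions per line, so E is only
reliably recovered to one step of the coarse excision grid
({0, 0.2, …, 1}); the high regime (E ≈ 0.9) is recovered to one coarse
step as well. Rate recovery at K ≈ 0.8 is reliable to ±0.1 with 107
observed lines and 1000 simulated lineages per grid point.

## Positional null and enrichment (`tedrift.enrichment`)

All coordinates are 0-based half-open internally; GFF3 is converted on
read. The null redraws n positions uniformly over the unmasked genome
(mask = pericentromere cores plus any user-supplied exclusions), exactly
respecting the mask by construction.

- **Metagene hierarchy.** Each site gets exactly one category by the
  stepwise rule 5'UTR > 3'UTR > exon > intron > intergenic; positions
  inside a gene body matching no annotated part default to intron.
  Intergenic sites carry a signed distance to the nearest gene
  (ties to the lower-coordinate gene): negative upstream of the TSS,
  positive past the 3' end, respecting strand.
- **Fold and empirical p.** fold = observed / null mean;
  p = (r + 1)/(N + 1) with r the number of null replicates at least as
  extreme. The default tail tests over-representation (r counts
  replicates with a count ≥ observed), which keeps the p-value
  distribution close to uniform under the null despite ties in integer
  counts (verified by a KS check); `less` and `two-sided` tails are
  available, the latter counting replicates by absolute deviation from
  the null mean (conservative under ties). Categories absent from both
  the observation and the null are reported as absent rather than 0/0.
- **Contingency tests.** Essential-gene and parental-origin contrasts use
  Pearson chi-square without continuity correction on 2×2 tables
  (df = 1); degenerate margins raise an error naming the margin.
- **Meta-profiles.** Windows (default 4 kb, offsets −w/2..+w/2) centred
  on sites; windows truncated by chromosome ends contribute only to the
  offsets they cover, so each offset's mean is taken over the windows
  available there (unbiased on toy genomes). Smoothing is a cubic
  smoothing spline with GCV-chosen penalty by default (a fixed penalty or
  a centred rolling mean can be configured); no bit-identity with any
  particular external smoother is claimed.
- **Dyad distances.** Per-site distance to the nearest dyad midpoint,
  unsigned by default (a signed variant reports site − dyad);
  equidistant ties go to the lower-coordinate dyad. Sites beyond
  `max_distance` (default 200 bp) are excluded and counted. The density
  is a histogram with 5-bp bins centred on multiples of the bin width,
  and the mode is the midpoint of the fullest bin — so a planted offset
  is recovered to within one bin width.

## Synthetic data (`tedrift.synth`)

The generators produce every input the pipeline consumes, with ground
truth recorded in sidecar files:

- **Toy genome** (default 2 × 200 kb — large enough for ~80 multi-exon
  genes and thousands of dyads, small enough that full pipelines run in
  seconds): genes with 5'UTR/exon/intron/3'UTR parts tiling each gene,
  chromatin states 1–9 tiled in 500-bp windows with exact per-state
  quotas (realised coverage matches the requested fractions to within
  one window), nucleosome dyads every 180 bp with ±10 bp jitter, a
  masked pericentromere core per chromosome, an alternating wt/ddm1
  parental mosaic, and Bernoulli essential-gene flags. Deterministic
  given the seed, byte-identical files on regeneration.
- **Planted insertion sets**: per-bp sampling weights multiply state
  weights, metagene-category weights, a Gaussian bump around a chosen
  dyad offset, and a pericentromere×ddm1 multiplier; the drawn sites
  carry truth columns for recovery tests. A planted per-bp weight w on a
  state covering fraction f of the unmasked genome yields an expected
  fold of w/(w·f + 1 − f), which the enrichment stage recovers.
- **Signal tracks**: flat baseline plus rectangular/triangular/Gaussian
  bumps anchored at TSSs, dyads or given positions; noise-free so tracks
  round-trip exactly through bedGraph.
- **Observation samples**: drawn from the simulation model at known
  (variant, K, E, l) with a JSON truth sidecar. Three presets mirror the
  qualitative regimes of the studied families: copia-like (K = 0.25,
  no excision, silencing at 40 new copies), vandal-like (K = 0.4,
  E = 0.05), enspm-like (K = 0.8, E = 0.92).

What passing tests show: the pipeline recovers parameters and planted
biases it generated itself, under the model's own assumptions (unlinked
loci, no selection, uniform positional null, single TE family). What they
do not show: robustness to detection noise, mapping artefacts, linked
insertions, selection against insertions, or census-timing effects in
real sequencing data.

## Problem sizes and numerical choices

Recovery experiments use 107 observed lines over six generations —
matching the observation scale the model targets — with 1000 simulated
lineages per grid point and 20 seeded repetitions per experiment;
plateau summaries use 1000 lineages over 14 generations. Property checks
run at 10^5 replicates with 3·SE Monte-Carlo bands. All stochastic entry
points take a seed or generator; identical seeds give byte-identical
outputs. Silencing thresholds must be integers ≥ 1 (or infinite);
empirical p-values are never zero by construction; degenerate inputs
(empty samples, fully masked genomes, zero-weight bias specs, all-zero
contingency margins) raise typed errors rather than returning NaNs.

## Known limitations

- The excision probability is weakly identified when K·E is small (see
  above); grid profiles are emitted so users can judge flatness.
- The Peacock statistic's lattice evaluation is exact for integer count
  data only; real-valued 2D samples would need the general
  continuous-anchor variant.
- The positional null is uniform over unmasked bp; GC, mappability or
  coverage biases of real detection pipelines are not modelled.
- Concerted silencing is a hard threshold; gradual or stochastic
  silencing onset is not modelled beyond the threshold rule.
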