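# Methods

This note documents the models, conventions and design choices behind
`salmonsnp`, in the order data flows through the pipeline.

## Data model and coordinate conventions

VCF positions are 1-based and BED intervals 0-based half-open; every
internal position is 1-based, with conversion only at the BED boundary
(`IntervalSet` stores intervals in BED coordinates and answers
membership queries for 1-based positions). Genotypes are dosage codes
0/1/2 with −1 for missing, so a subgroup's alternate-allele count is a
plain sum over non-missing cells and the allele number is twice the
non-missing count. Caller VCF dialect differences are normalized at read
time; no caller-specific logic survives past `variant_io`. Per-allele
read depths (AD) are mandatory on input because genotype re-calling is
defined on read counts; records without them are rejected rather than
imputed. Indel representation: any record whose reference or alternate
allele is not a single base is an indel (symbolic alleles: "other").
QUAL passes through htslib as a 32-bit float; reading recovers the
decimal printed in the file to six significant digits so that
write → read → write round trips are byte-stable.

## Filtering cascade

The six screens and the DH-heterozygosity filter are pure, idempotent,
site-local set filters, so the final set is the conjunction of the
predicates and is invariant to stage order; the implementation keeps a
fixed narrative order only for the per-stage accounting
(`FilterReport`, which satisfies in − removed = out at every stage).

Threshold semantics, chosen to match the stated rules literally:

- QUAL is a strict comparison (keep iff QUAL > 30); depth is inclusive
  (keep iff total depth ≤ 3,000).
- The 3,000-read cap applies to the caller-reported site-level total
  over all 115 samples (DP-style), not per sample: 3,000 ≈ 1.4× the
  expected ~2,130 total reads at 18.5× mean coverage, consistent with an
  excess-total-depth repeat screen.
- Indel proximity is measured from the SNP position to the nearest base
  of the indel's reference span [pos, pos + len(ref) − 1], boundary
  inclusive: gap ≤ 5 removes, and a SNP inside a deletion span has gap
  0. Each caller's own indel calls define its exclusion zones.
- Genotype re-calling: alternate allele present iff ≥ 2 supporting
  reads, reference present iff ≥ 1; both → het, one → the matching
  homozygote, neither → missing. The rule is applied to every sample
  (it does not merely veto heterozygotes), which is one of the readings
  the thresholds admit; the four-way table is exhaustively tested.
- Missingness is counted after re-calling, over the 80-fish NA
  discovery panel by default (≥ 79 callable genotypes per site); the
  roster subset is a parameter.
- A site heterozygous in *any* DH line is removed; missing DH genotypes
  never trigger removal. With no DH samples the stage warns and passes
  through.

Cross-caller site identity is exact (chrom, pos, ref, alt) equality.
No left-alignment pass is applied because only single-base SNPs reach
the intersection and those have a canonical representation. Genotypes of
the consensus set are taken from one designated reference caller (first
caller label in sorted order, i.e. freebayes); genotype disagreement
with the other two callers is counted and reported but not reconciled.

## Population-genetic statistics

Missing genotypes are excluded from all counts; nothing is imputed.
A site is polymorphic in a subgroup iff both alleles are observed there.
In the per-strain summary tables, the site count is the number of sites
with ≥ 1 non-missing genotype in the group, and average MAF and average
observed heterozygosity are taken over the group's polymorphic sites
only (the same convention for both, since polymorphism is the stated
scope of the heterozygosity average). MAF histogram bins are
right-closed with width 0.025 over [0, 0.5] (MAF 0 falls in the first
bin); width and the high-MAF cut (0.25) are parameters.

The Fst estimator is Weir & Cockerham (1984), two populations, per
site, with the observed-heterozygosity correction — the formulation
used by vcftools' `--weir-fst-pop`. The components a, b, c are
evaluated in exact rational arithmetic (`fractions.Fraction`) on the
integer allele and heterozygote counts, which makes θ = 1 at a fixed
difference an identity rather than a floating-point coincidence; the
float transcription of the same formulas agrees to ≥ 10 significant
figures and serves as the independent oracle in tests. With one
individual per population the finite-sample corrections are 0/0; they
vanish identically at a fixed difference (handled exactly) and the
estimator is reported as undefined otherwise, as it is when
a + b + c = 0 (site monomorphic in the pooled sample) or when a group
has no data. Panel membership ("Fst = 1") is decided by the
combinatorial fixed-difference condition itself, never by float
equality. The European comparison group is explicit input (default: the
31 wild European fish, not the DH lines), so the wild-group size is
never hard-coded.

## Phylogeny

Preprocessing follows the published tree protocol: restrict to named
chromosomes (parameter; the simulator has no unplaced scaffolds), keep
sites with MAF strictly > 0.1, and thin by LD. The published pipeline's
exact pruning algorithm is not specified, so a standard greedy windowed
scan is used: windows of 50 SNPs advancing by 5, earlier site retained
on conflict, guaranteeing that every retained pair within a window has
r² ≤ 0.1 (r² is the squared Pearson correlation of dosage codes over
pairwise-complete samples; pairs with undefined r² are never pruned).
Window size and step are exposed in `LDPruneConfig`.

The original study built its tree with maximum likelihood (DNAML via
SNPhylo). This package deliberately substitutes neighbor-joining on
allele-sharing distances (mean |dosage difference| / 2 over co-observed
sites) with a site-resampling bootstrap, which is sufficient for the
strain-level clustering claim the tree supports; the method is recorded
in `PhyloResult.method` and in run reports. The allele-sharing distance
satisfies symmetry and identity but not the triangle inequality, which
NJ does not require. Ties everywhere break by input order, making the
tree deterministic given the matrix. Bootstrap resamples sites (not
samples); supports are percentages of replicates containing each
non-trivial bipartition of the reference tree, with bipartitions
canonicalized against the alphabetically first sample.

## Simulator

The generator's job is to produce inputs whose correct handling is
known in advance, at the study's shape: 115 samples (GNB 16, PR 11,
SJR 53 with their year-class splits, 31 wild European, 4 European DH),
three callers, ~19–20k sites over 3 × 1 Mb chromosomes, 18.5 mean
per-sample depth (negative binomial, dispersion 8).

The genome is tiled (2 kb tiles) into low-complexity mask (30%),
homeologous blocks (25%, echoing the genome fraction in
high-similarity chromosome-arm pairs), collapsed-repeat blocks (2%) and
free sequence; candidate site slots sit on a 15-bp grid away from tile
edges so placements are collision-free and ordinary SNPs never fall
within the indel-exclusion distance of each other. The masked fraction
is deliberately smaller than the ~60% repetitive fraction of the real
genome: the BED input of the real pipeline covers only
RepeatMasker-flagged low-complexity sequence, and a larger mask would
only shrink the usable toy genome. Each artifact class exercises
exactly one screen (multi-allelic and indel records the bi-allelic
stage, near-indel SNPs the proximity stage, masked SNPs the mask stage,
excess-depth sites the depth cap, PSVs the DH filter), which is what
makes set-exact truth-recovery assertions possible.

Allele frequencies are nested Balding–Nichols draws: ancestral
p ~ Beta(0.4, 0.4) (chosen so the simulated panel's high-MAF share comes
out near the ~23% observed in real consensus sets), continent-level
divergence F = 0.20, strain-level founder effects F = 0.15 / 0.12 / 0.04
for GNB / PR / SJR (the two small strains had few founders; SJR many),
year-class drift F = 0.02. Frequencies are clipped to [0.02, 0.98]
before sampling so "clean" sites rarely drift to chance fixation;
truth-recovery checks nevertheless score the diagnostic screen against
fixed differences computed from the *true genotype matrix*, so any
chance fixation is part of the truth, not a false positive. Genotypes
are Hardy–Weinberg within terminal groups; DH samples draw one allele
and double it. PSV sites are heterozygous in every sample — the
genotype-level signature of duplication collapse. Modelling the
artifact at genotype level rather than simulating reads and mismapping
is sufficient because the pipeline consumes VCFs, not reads.

Caller emulation is independent Bernoulli per site (sensitivity),
plus false-positive sites, per-genotype error and missingness, and a
QUAL distribution with a configurable sub-threshold fraction; the
default profiles rank the callers like their real counterparts
(mpileup most permissive, freebayes least). Allelic depths are always
consistent with the emitted genotype under the re-calling rule: the
emitted GT *is* the re-call of the emitted AD, so a sampled depth too
low to support the intended genotype yields a missing call — the
realistic low-coverage failure mode. Correlated caller errors are not
modelled (documented limitation). An optional LD mode copies genotypes
between adjacent ordinary SNPs with a per-sample switch probability, to
give the pruner something to prune; it is off by default and never
touches planted fixed differences or artifact classes. Everything is
driven by one seed through spawned, per-caller independent streams;
identical config + seed gives byte-identical output files.

`SimConfig.noiseless()` is the error-free preset (sensitivity 1, no
false positives, no genotype noise, depths floored at 6 reads so no
call is missing); under it the final consensus equals exactly the
planted clean + continental-fixed sites and the diagnostic screen has
precision = recall = 1.

## What passing tests do and do not show

The simulator validates the *logic* of every screen and estimator under
known truth; it does not reproduce real caller error correlation,
alignment artifacts beyond the genotype-level PSV signature,
recombination-scale LD, or reference-genome idiosyncrasies. Results on
real data therefore inherit only the pipeline's correctness guarantees,
not the simulator's recovery rates. Test and report problem sizes
(compact 2 × 100 kb genomes for most fixtures, the full default scale
for truth-recovery and tree checks, 100 bootstrap replicates instead of
the 1,000 a production run would use) were chosen as the smallest sizes
at which each property is sharply testable.

## Numerical choices and degenerate inputs

- Exact rational arithmetic for Fst components; floats elsewhere.
- `wc_fst` returns undefined (None) rather than raising on degenerate
  sites; `pairwise_distance` raises, naming the pair, if two samples
  share no co-observed site; an all-zero distance matrix yields a star
  tree with a warning; an empty post-MAF matrix is a hard error.
- LD pruning never drops a pair whose r² is undefined (zero variance or
  < 2 complete pairs).
- Venn regions are keyed by sorted caller labels; all reports serialize
  with sorted keys so byte-level reproducibility holds end to end
  (wall-clock timings are written to a separate file for the same
  reason).
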