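# Methods

## Model and rationale

The scan targets a specific population-genomic signature.  Across a hybrid
zone, gene flow homogenizes most of the genome between parapatric races,
while loci controlling the divergent phenotypes stay differentiated; and
between comimetic species, wing-pattern alleles can be identical by
descent through introgression or ancestral polymorphism.  At such loci the
local genealogy departs from the species tree: the two phenotype-sharing,
non-sister taxa become monophyletic while everything else stays put.
Topology weighting makes this quantitative: a window tree with several
tips per taxon group is decomposed into the distribution of unrooted
six-group topologies obtained by picking one tip per group, and the
shared-ancestry signal is the summed weight of the five topologies in
which the focal pair is a cherry and the induced four-group topology
equals the species tree (five, because the cherry can attach to any of the
five edges of the four-taxon species tree).  A weighting of 1 means every
subtree supports shared ancestry; 0 means none does.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| min depth / min GQ | 5 / 20 | calls below either are set missing |
| min minor-allele count | 2 | over observed allele copies; removes singletons and monomorphic sites |
| max site missingness | 0.10 | fraction of all samples |
| window size / step | 100 / 25 | SNP-index windows on the filtered site list |
| min SNPs per sample | 30 | non-missing calls per tip required to build a window tree |
| sampling CI | Wilson 95%, full width < 0.05 | stopping rule for Monte-Carlo weighting |
| exact-enumeration limit | 100,000 | combination-space size below which weighting is exact |
| peak threshold | 0.95 (CLI default); 0.9 used for synthetic recovery; 1.0 available | on the smoothed track |
| diagnostic-scan missingness cap | 0.20 | over contrast-group samples |
| SNP cluster gap | 5 kb | single-linkage joining distance |

The minor-allele rule is implemented as a *count* (< 2 observed copies)
rather than a per-site frequency: a count threshold stays well defined
when calls are missing, and matches a 2-of-106-copies frequency cut on a
fixed 53-sample panel.  The missingness denominators differ deliberately:
site filtering uses all samples, the diagnostic scan uses only the
contrast groups (excluded taxa removed), which is the reading that keeps
the scan usable when many unrelated samples are present.

## Design choices where the design was open

**Tip resolution.**  Tree building needs one sequence per tip.  Diploid
calls are pseudo-haploidized: homozygotes copy their allele, heterozygotes
pick one allele uniformly at random using a generator seeded per cell by
(seed, site index, sample index), so the result is reproducible and
independent of processing order.  Phasing is deliberately not attempted; a
two-tips-per-sample mode would be a straightforward extension.

**Tree builder.**  Neighbor joining on Hamming-proportion distances
(pairwise-complete sites, no substitution-model correction) replaces
likelihood-based inference.  Topology weighting consumes only the tree
shape, and NJ is consistent on additive distances, so grouping signal
survives; the newick-ingest path lets users substitute externally built
maximum-likelihood trees per window.  Ties in the Q criterion join the
lexicographically lowest index pair and negative branch-length estimates
are clamped to zero, making output deterministic.

**Stopping rule.**  The Monte-Carlo weighting stops when the Wilson 95%
interval around every topology weight has full width < 0.05.  Wilson is
used because the normal approximation collapses to zero width at observed
proportions of 0 or 1 — where most of the 105 weights sit — and would stop
after a single draw regardless of sample size.  At p̂ ∈ {0, 1} and
n = 100 the Wilson full width is ≈ 0.037, so a perfectly concordant tree
legitimately stops after one 100-draw batch.

**Canonical topology identity.**  Topologies are identified by their set
of non-trivial bipartitions (each side oriented away from the smallest
label), which is a perfect invariant for unrooted trees; the printable
canonical id is the newick string rooted on the smallest label's pendant
edge with recursively sorted children.  Tests verify the identity against
a graph-isomorphism oracle over the full 15-topology five-label
enumeration.

**Smoothing and peaks.**  The smoothed value of each 25-SNP region is the
mean of all (≤ 4) windows covering it; scaffold edges average over the
available windows without padding.  Peaks are maximal runs of regions at
or above the threshold, reported in genomic coordinates of the bounding
SNPs.  An exact-equality threshold of 1.0 is fragile under sampling noise,
so the CLI default is 0.95 with 1.0 available by flag.

**Element delimitation.**  When previously published intervals are
supplied, consistent peaks are clipped to the prior they overlap and peaks
overlapping no prior are dropped (the search is constrained to those
regions); elements without diagnostic-SNP support are kept but flagged.
Splitting of co-located signals is delegated entirely to the peak caller's
gap behavior — the delimiter never merges across a dip.

## The synthetic-data generator

The simulator emulates exactly the features the scan keys on, and nothing
else.  The genome is a row of `n_blocks` blocks of `block_length_snps`
sites.  Each block draws one genealogy over the six groups: the species
topology with probability 1 − `ils_rate`, otherwise a uniformly random
alternative topology (background ILS); inside an implanted tract the
genealogy is forced to the species tree with the recipient re-attached as
the donor's sister.  Every branch of the group tree (9 edges) and every
haplotype's pendant branch receives Poisson(`branch_scale`) mutations at
distinct sites within the block; when mutation events exceed the block
length — which happens at the default density — a uniformly random subset
of events the size of the block is kept, so the block saturates instead of
violating infinite sites.  Two independently simulated haplotypes pair
into each diploid sample, which is where heterozygosity comes from.
Missing calls and sub-threshold DP/GQ calls are injected at the configured
rates.  Identical seeds give byte-identical VCF output.

Defaults — six groups of three diploid samples, 200 blocks × 100 SNPs,
`ils_rate` 0.2, one 8-block tract, `branch_scale` 3, 2% missing and 2%
low-quality calls — are the reference operating conditions for the
recovery and null-control tests.

What the generator does **not** emulate: recombination within blocks,
coalescent branch-length variation, realistic allele-frequency spectra,
selection, or the linkage structure of real chromosomes.  Passing the
recovery tests therefore shows the scan correctly converts local genealogy
structure into called intervals, not that it would have equal power on any
particular empirical dataset.

## Detectability limits and known behavior

A tract is called at threshold 0.9 only if some region has (nearly) all
of its ≤ 4 covering windows fully inside the tract, which requires about
`size + 3·step` = 175 consecutive post-filter SNPs of pure signal.  Under
the default conditions a tract of 8 × 100 raw SNPs retains ~160–200
filtered SNPs (haplotype-pendant singletons are removed by the
minor-allele filter, and saturation trims group-level mutations), so
recovery sits safely above — but not infinitely far above — this
threshold; occasional random seeds fall just short.  Boundary error is of
order half a window (~1–3 kb at default site spacing) because smoothing
blurs tract edges.  Single ILS blocks whose random genealogy happens to be
a target topology span only ~25 filtered SNPs, never dominate a window,
and are correctly absent from the peak calls — this is what keeps
precision near 1.

Degenerate inputs: windows where any tip pair shares zero called sites are
skipped with a log entry; trees with fewer than four tips, polytomies, and
unknown tip labels are rejected with errors naming the offending window;
an absent region scaffold returns an empty matrix with a warning rather
than an error.
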