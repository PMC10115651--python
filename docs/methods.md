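# Methods

`metevol` analyses the timing and mode of metastatic divergence from
multi-region tumour sequencing summarised as mutation-cluster trees, and
provides a spatial agent-based model relating divergence timing to
primary tumour size. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Input model

The substrate is a rooted tree of mutation clusters per case. Each
cluster carries a mutation count and a phylogenetic cancer cell fraction
(phyloCCF) per sample — the fraction of cancer cells in that sample
carrying the cluster's mutations, as a tree-aware point estimate.
Samples are primary tumour regions, primary lymph-node/satellite
lesions, or recurrence/progression samples; the latter two form the
"metastasis" group. Mutation-level clustering and tree building are
upstream of this package (any tool producing clustered CCFs will do);
only the default tree topology is used except where origin calls are
checked across alternative topologies.

Per-region clonality is thresholded on the phyloCCF point estimate:
clonal at CCF >= 0.9, absent below 0.05, subclonal in between. Both
thresholds are configuration parameters, since upstream pipelines differ
in whether they classify on point estimates or confidence intervals;
the defaults are deliberate stand-ins for a CI-based rule and all
downstream logic is threshold-agnostic. Point-estimate overshoots
(CCF > 1, up to 1.5 accepted on input) are clonal; CCFs are capped at 1
only inside clone-proportion estimation. Tumour-level (group) status is
clonal iff clonal in every sample of the group, absent iff absent in
all, subclonal otherwise.

## Divergence timing

The phylogenetic method counts mutations in clusters clonal across all
primary regions, and computes the fraction of them also clonal in a
metastasis sample. A fraction below one means a clonal sweep completed
in the primary after the metastatic lineage branched ("early"
divergence); a fraction of one means no sweep followed ("late"). The
comparison tolerance is 1e-9: the fraction is a ratio of integer
mutation counts, so it is exact unless CCF noise flips a clonality call
upstream. Case-level timing is early iff any metastasis sample is
early. Three orthogonal read-outs — region-based mutation presence with
LOH-locus filtering, primary-ubiquitous arm-level allele-specific LOH
(>= 75% of the arm lost, same allele in every primary region), and
shared whole-genome-doubling identity — exploit the irreversibility of
loss events: a metastasis lacking a primary-clonal loss must predate
it.

Downsampling enumerates every k-subset of primary regions exhaustively
(region counts in cohorts of this kind are <= ~10, so C(n,k) is small),
recomputes the subset-clonal cluster set and the shared fraction per
metastasis, and averages over subsets. A cluster that is clonal in one
region but subclonal or absent elsewhere (the "illusion of clonality")
enters the subset-clonal set at small k and, when absent from the
metastasis, misclassifies a late case as early.

## Dissemination and seeding

A metastasis is monoclonal if every cluster shared with the primary is
clonal within it, polyclonal if any shared cluster is subclonal; a case
with several monoclonal metastases is still polyclonal when their
shared-cluster sets differ. Origin is monophyletic iff the shared
clusters lie on one root-to-leaf path; a monoclonal metastasis is
monophyletic by construction. When a case has alternative tree
topologies, the origin call is made on each; disagreement yields
"uncertain".

Seeding clusters are found leaf-up on the shared subtree. The deepest
shared cluster of every branch is always a seeding cluster (its clone
demonstrably reached the metastasis). If it is subclonal in the
metastasis the walk ascends: intermediate ancestors are seeding when
their metastasis CCF strictly exceeds that of their path child (an
ancestor at equal CCF adds no evidence of an independent seeding
clone); where branches converge the children's CCFs are summed before
the comparison; the first ancestor clonal in the metastasis is always
seeding and terminates the branch. Reaching the root without a
met-clonal cluster is an error, since the root is clonal everywhere by
construction.

Clone proportions per sample are estimated bottom-up: a leaf clone's
proportion is its phyloCCF; an internal clone's is its phyloCCF minus
the sum over its *direct children* (subtracting all descendants would
double-count). Clonal clusters are first corrected to CCF exactly 1 and
all CCFs capped at 1; negative internal proportions arising from point-
estimate noise are clamped to zero and the vector renormalised. The
dispersion index of a cluster with regional CCFs x_i is
D = 1 - (max(p_i) - 1/n) / (1 - 1/n) with p_i = x_i / sum(x): 1 for an
evenly spread clone, 0 for a region-private one; undefined for n = 1.

## Selection analyses

Paired mutation favouring uses tumour-level clonality: a cluster is
metastasis favoured when its clonality is higher in the metastases than
in the primary, primary favoured when lower, maintained otherwise (all
nine status pairs are covered); the metastasis side takes the maximum
clonality across metastasis samples. Cluster labels propagate to member
mutations; non-driver mutations supply the background proportions
(mutation-weighted). Per gene with >= 5 driver mutations, a multinomial
goodness-of-fit test compares the favouring counts with the background:
the p-value is the null probability of an outcome at most as probable
as the observed one, computed by full enumeration for totals <= 12 and
by seeded Monte-Carlo (default 1e5 draws, add-one estimator) above;
Benjamini-Hochberg correction is applied across tested genes. Because
the statistic is discrete, p-values are conservative at small totals;
the calibration study therefore assesses uniformity in the
larger-count regime (~100 events/gene), where the staircase is fine,
and this is the regime the uniformity result speaks to.

SCNA events are called per gene against sample ploidy at +-0.5 on
log2(CN/ploidy) (configurable; the cut-off stands in for the published
convention this classification usually cites). Paired SCNA favouring
counts a tumour only when the event appears in at least one of its
samples, and uses presence-in-group logic with the same multinomial
machinery (>= 5 tumours per gene). G-scores per gene are taken from
GISTIC-style segment score tables by length-weighted overlap, with the
mean of the two flanking segments for genes in score gaps; the G-score
difference (metastasis minus non-metastatic cohort) is reported for
genes significant in the metastasis cohort. dN/dS odds ratios consume
externally computed per-gene estimates (seeding versus combined
primary-unique/non-metastatic mutation sets): OR > 2 is seeding
favoured, OR < 0.5 primary favoured, otherwise both; dNdScv and
GISTIC2.0 themselves are never re-implemented.

## Agent-based tumour model

Cells live in demes of capacity 5,000 on a 3D cubic lattice, tracked as
genotype counts (never per-cell objects; the update rules are
distributionally equivalent to per-cell semantics). Per synchronous
sweep, each cell attempts division with probability
(fitness / max fitness in deme) x (1 - occupancy / capacity); an
attempting cell divides with probability 0.8 and dies with probability
0.2 (the fixed death rate is applied per division attempt: coupling
death to proliferation keeps crowded demes quiescent rather than
shrinking, and lets demes actually reach capacity — a baseline
per-sweep death combined with the density gate has a stable equilibrium
at ~0.75x capacity, at which demes would never fill and never split).
A deme reaching capacity splits, a random half of its cells founding an
empty neighbouring site. By default growth is *peripheral*: an
enclosed deme stays quiescent, preserving the spatial sector structure
that multi-region sampling relies on; a volumetric mode ("budge",
shifting demes towards the nearest empty site along a random direction)
is available in configuration.

Each division acquires Poisson(0.4 or 0.6) new exome mutations. Fitness
effects follow an asymmetric Laplace distribution centred at zero:
exponential branches with mean -s (deleterious) and +s/2 (beneficial),
where the global selection coefficient s (default 0.01) controls the
spread; the sign probabilities follow the continuous-density convention
P(positive) = mean_pos/(mean_pos + mean_neg), i.e. 1/3 for mutations
and 1/4 for events (the branch means are prescribed, the mixture
weights are not; this is the unique choice with a continuous density at
zero). A mutation is a driver with probability 1e-5, contributing a
fixed +10s and switching on susceptibility to large genomic events,
which then occur with probability 0.3 per division with broader effects
(+s / -3s branch means). Fitness composes multiplicatively.

Metastases are founded by 1-100 cells drawn from surface demes of one
or three source regions when the primary first crosses a prespecified
size; a founded metastasis that goes extinct is re-run from the same
founder cells (an observed metastasis is by definition one that
survived). Whole-exome sequencing is emulated per sampled region
(contiguous surface-seeded deme patches of ~50,000 cells in distinct
octants): every mutation is heterozygous-diploid (true VAF = half the
carrier fraction), depth is Poisson(400), alt counts binomial at the
error-adjusted VAF (substitution error 1e-3/bp), and records need >= 2
alt reads and observed VAF >= 0.02 to be reported. Variants below a
true-VAF floor of 0.005 cannot pass this filter at the default depth
and are not read-simulated. Simulated timing uses the sequencing-level
rule: mutations with VAF > 0.3 in at least 90% of primary regions are
primary-clonal; a pair is late iff all of them are detected in the
metastasis. Cell counts convert to diameter via cubic cells of 15 um
side, dividing by purity first and reporting the side of the equivalent
cube (the sphere-equivalent convention gives ~16 mm for the worked
2.5e8-cell example and is rejected by its printed 12-13 mm bracket).

### Scaled experiments and what they can and cannot show

The reference configuration (1e9 cells, 20 replicates per condition) is
a cluster-scale computation. The packaged experiments run at 1e6-1e7
cells. Two quantities do **not** survive naive downscaling, and the
experiment sizes were chosen with this in mind:

* *spatial resolution*: sector structure lives in deme units; 1e9/5,000
  is ~200,000 demes whereas 1e7/5,000 is ~2,000. Runs that need
  regional heterogeneity (e.g. the pipeline bridge demonstration) can
  scale the deme capacity down to keep the deme count realistic.
* *late clonal sweeps*: the probability that a mutation newly reaches
  the primary-clonal threshold between divergence and resection grows
  with the number of generations and driver events, both of which
  collapse with tumour size. At desk scale the early-versus-size signal
  is carried almost entirely by early lineage drift: lineage extinction
  resolves within the first tens of cells, so divergence inside that
  window loses later-fixing mutations while later divergence does not.
  The scaled experiment grid therefore reaches down to few-cell
  divergence sizes, and reproduces the *qualitative* monotone decline
  of the early fraction with size at magnitudes well below the
  full-scale figures. The full-scale fractions themselves are not
  reproducible at desk scale and are not claimed.

The synthetic-data generator (cluster-tree cohorts) is the primary test
substrate instead: clone proportions are drawn per sample and CCFs
computed as subtree sums, so the sum rule holds exactly before noise;
early/late, mono/polyclonal and mono/polyphyletic labels are built into
the construction (trunk clusters clonal everywhere; early metastases
branch from an internal trunk cluster; polyclonal metastases keep a
shared cluster subclonal; polyphyletic ones are seeded from two sibling
branches), and Gaussian CCF noise is truncated to [0,1] (mildly biasing
near the boundaries, documented rather than re-drawn). What passing
round-trip tests show is that the classifiers invert this generative
construction exactly in the noiseless regime and degrade gracefully
under point-estimate noise; they do not show robustness to upstream
clustering errors, copy-number artefacts, or non-Gaussian CCF error,
none of which the generator emulates.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.Generator` seeds given
explicitly; cohort generation, simulation and Monte-Carlo tests are
bit-reproducible under a fixed seed (the simulator's inner sweep kernel
is seeded per sweep from the tumour's generator). Sets are emitted in
lexicographic order and writers sort keys, so identical seed and
configuration give byte-identical outputs. Genomic segments are 0-based
half-open; mutation positions 1-based. Ties: the seeding walk uses
strict ">" for ancestors; clonality boundaries are >= clonal_min and
< absent_max. Degenerate inputs return explicit undefined markers
(dispersion with one region; region-based timing with an empty
filtered mutation set) rather than raising.

## Known limitations

* Clonality thresholds on point estimates are a stand-in for upstream
  CI-based rules; cohort-level fractions depend on them.
* The simulator has no copy-number or WGD bookkeeping (genomic events
  affect fitness only), no therapy effects, and is not fitted to any
  cohort.
* MACHINA-style migration-history inference is out of scope; the
  package only prepares clone-proportion inputs in a compatible layout.
* dN/dS and GISTIC layers consume precomputed estimate tables; their
  internals (trinucleotide models, peak calling) are delegated to the
  original tools.
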