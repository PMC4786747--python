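# Methods

`cladewane` analyses the decline and extinction of a fossil clade from four
kinds of input — a rooted cladogram, a discrete morphological character
matrix, a stratigraphic range table (first/last appearance ages, FAD/LAD,
in Ma), and per-bin occurrence/environmental series — and ships a synthetic
-clade generator whose ground truth is used to validate every stage.  This
note records the models, the conventions and defaults that matter, and the
choices made where the design was genuinely open.

## Age and bin conventions

Ages are in Ma and decrease toward the present.  All per-bin counting uses
one half-open convention: a bin with boundaries `older > younger` covers
ages `a` with `older >= a > younger`.  A boundary age therefore belongs to
the younger-side bin, every age inside a `BinSequence`'s span belongs to
exactly one bin, and the bin durations sum to the span.  A taxon's range is
the closed interval `[lad, fad]`; gaps within it are ranged through
(Lazarus treatment).  Stage-level quantities can be apportioned to substages
in proportion to substage duration (`apportion_to_substages`), conserving
the stage total.

Polymorphic or uncertain character scorings (`{01}`-style) are mapped to
missing on input.  Nothing downstream attempts to exploit a polymorphic
set; this is the conservative reading and it is applied uniformly.

## Tree timescaling

Two a-posteriori timescaling rules are implemented:

* **basic** — every internal node is dated at the oldest FAD among its
  descendant tips.  This is the unique dating minimising total implied
  branch duration subject to `parent age >= child age` and
  `node age >= descendant FADs` (each node independently takes its smallest
  feasible value), hence the minimum-ghost-lineage / minimum-diversity
  solution.  Zero-duration branches are an unavoidable artefact: under this
  rule every internal node has at least one child at its own age.
* **equal** — starting from the basic dating (root optionally pushed older
  by `root_buffer`, default 0), zero-duration branches borrow time from the
  first ancestral branch of positive duration: the positive branch plus the
  `k` zero branches chained below it are respaced to `d/(k+1)` each.
  Chains are processed deepest-first, so a full chain claims its share in
  one step and sibling zero branches then draw from the updated ages; the
  procedure is deterministic.  Tip ages and the root age never move, so
  root-to-tip path lengths are conserved exactly, and node ages only move
  rootward relative to basic.  Zero branches hanging directly under a root
  stack at the oldest FAD have nothing to draw from and legitimately stay
  at zero (this occurs for the oldest tip when `root_buffer = 0`).

Polytomies are dated by the same rules without resolution.  Bayesian
(morphological-clock) dated trees are not inferred here; externally dated
trees can be read in and used by all downstream counting.

## Diversity

Taxic diversity (TDE) is the per-bin count of taxa whose range-through
interval meets the bin.  The phylogenetic diversity estimate (PDE) counts
lineages on a timescaled tree: a terminal branch contributes the interval
from its origin (parent node age — the start of its ghost lineage) down to
the taxon's LAD, and internal branches contribute their duration intervals.
Zero-duration internal branches are excluded: they are point events, and
counting them would double-count a lineage at an instant (it would also
break the degenerate equivalence PDE = TDE when all FADs coincide).  Taxa
absent from the tree are added by their observed ranges, so unplaced valid
taxa still contribute.  Because a terminal branch interval contains the
taxon's range, PDE >= TDE bin by bin whenever all ranged taxa are tips.
Across a tree set (source trees x timescaling methods) the median and the
2.5/97.5 percentiles are reported.  PDE fills ranges backwards only — a
lineage still ends at its last appearance — so young-edge effects remain.
An optional tips-only mode drops internal branches for the alternative
convention in which ancestors are not counted as lineages.

## Disparity

**Pairwise dissimilarity** between two taxa is the mean per-character
difference over characters scored in both: an unordered character
contributes 0/1, an ordered one `|a-b| / state range` (range taken over the
observed column).  Each pair carries a weight equal to its number of
comparable characters; pairs with none are undefined rather than guessed.
Per bin, the weighted mean (or median) over pairs of co-binned taxa is
reported with a bootstrap 95% interval (resampling taxa within the bin;
default 10,000 replicates, seeded).  Bins with fewer than two taxa are
undefined.

**Ancestral reconstruction** extends the matrix with one row per internal
node, filled only where the reconstruction is unambiguous.  The full set of
most-parsimonious reconstructions per character is characterised exactly by
a Sankoff down/up pass over the step-cost matrix (0/1 for unordered —
Fitch; `|i-j|` for ordered — the Farris interval method): a state is in a
node's MPR set iff fixing the node to it still attains the global minimum
cost, and a node is assigned a state only when that set is a singleton.
Missing tips contribute zero cost everywhere.  The implementation is tested
against exhaustive enumeration of all internal assignments on trees up to 6
tips and 4 states.  Reconstruction can only reduce or preserve the missing
fraction relative to blank ancestor rows; the size of the reduction depends
on matrix density.

**Sum of variances** runs classical PCoA (double-centre `-D²/2`,
eigendecompose) on the same character dissimilarity computed on the
tips+ancestors matrix.  Reusing one distance definition keeps the pipeline
self-consistent; rows still undefined after reconstruction are pruned and
reported.  Negative eigenvalues (possible for non-Euclidean character
distances) are dropped and variance fractions reported over the positive
spectrum — the simplest defensible convention.  Scores are eigenvectors
scaled by the square root of their eigenvalues, so the sum of score
variances over all positive axes equals total variance (checked to 1e-9).
The axis count is the smallest `k` reaching a target variance fraction
(default 0.95).  Per bin, the variances of the first `k` axis scores of the
rows present are summed (ddof = 1): tips are present by their ranges,
ancestral rows over their subtending branch's interval.  Bootstrap CIs
resample rows within the bin.  Reference values over a named bin subset are
unweighted means of the defined bins (`interval_average`).

## Rates

Cladogenesis events are internal-node ages; extinction events are
range-through LADs; both are counted per bin with the standard half-open
convention and summarised across the tree set by median and range.  Rates
default to raw counts, with per-My normalisation available because bin
durations differ.  Per-lineage ("relative") extinction is
`100 x extinctions / lineages present` (PDE denominator by default);
turnover is cladogenesis plus extinction.  Per-branch character rates are a
parsimony surrogate, not a Bayesian clock: changes between reconstructed
branch endpoints (ordered: summed state distance; unordered: inequality
count) over branch duration, skipping characters missing at either endpoint
(a conservative undercount) and excluding zero-duration branches.

## Ecomorph guilds

Traits are centred and scaled to unit variance (ddof = 1; constant or
missing columns are errors), converted to Euclidean distances, and
clustered by Ward's minimum-variance method (heights on the distance
scale; the implementation is checked against a brute-force greedy
minimum-variance merger for up to 7 points).  Cluster support uses the
multiscale bootstrap: trait columns are resampled with replacement to
`round(r x n_traits)` for scales `r` in 0.5–1.4 (step 0.1, >= 100
replicates each), each original cluster's recovery frequency `BP_r` is
probit-transformed, and `z(r) = v*sqrt(r) + c/sqrt(r)` is fitted by
weighted least squares with binomial weights; the approximately unbiased
support is `AU = 1 - Phi(v - c)` and BP is the recovery frequency at
`r = 1`.  When recovery is constant across scales the two-term basis is
degenerate (it cannot represent a constant); the boundary is then treated
as flat (`c = 0`), which makes AU coincide with BP — in particular a
cluster recovered in every replicate gets AU at the clipping limit rather
than a fit artefact.  Clusters never recovered at any scale get AU = 0 with
a flag.  With only seven traits the resample sizes span 4–10, so AU values
are indicative rather than sharply calibrated; this small-feature regime is
inherent to resampling features of a 7-trait table.  Guilds are cut either
to exactly `k` clusters or as maximal non-root clusters with AU above a
threshold (unclaimed taxa become singletons); guild occupancy per bin
counts distinct labels among range-through taxa.

## Extinction timing

With `N` independent sampling opportunities (suitable formations) and a
per-formation occurrence frequency `f`, the probability of total absence is
`(1-f)^N`; inverting at probability `p` gives the largest frequency
consistent with observing nothing, `f = 1 - p^(1/N)`.  Range extensions
under constant recovery come in two forms, both reported and labelled: the
classical horizon-count formula `R((1-C)^(-1/(H-1)) - 1)` and a rate-based
Poisson variant `-ln(1-C)/lambda` for when a per-My recovery rate is the
better-constrained input.  The Poisson variant's coverage is validated
against the generator's homogeneous-Poisson preservation (95% nominal,
checked within ±2%).

## Environmental correlation

Generalized differencing detrends a series on time (bin midpoints — the
symmetric choice of time covariate), estimates the lag-1 autocorrelation
`rho` of the residuals, and analyses `d_t = r_t - rho * r_{t-1}`.  Pairwise
tests are two-sided Pearson on the differenced series (t distribution,
n-2 df; Spearman available).  Model comparison fits, by maximum likelihood,
`y = b0 (+ b1 x) + AR(1) errors` with `phi` profiled on (-0.999, 0.999)
via the Prais–Winsten transform, for each single predictor plus an
intercept-only model whose `phi` spans stationary noise through a near
random walk.  Parameter count includes the betas, `phi` and `sigma²`;
models are ranked by `AICc = -2lnL + 2k + 2k(k+1)/(n-k-1)` with Akaike
weights.  Confidence intervals: Wald for the betas (GLS covariance with a
finite-sample variance correction), profile-likelihood inversion for `phi`
(Wald on `phi` is noticeably anticonservative at moderate n).  The same
battery runs on labelled bin windows (e.g. full vs truncated before the
terminal bin); windows under 5 bins are skipped.  Multiple-testing
correction is off by default (raw pairwise comparisons are reported);
a Benjamini–Hochberg annotation can be applied downstream.

## Synthetic clades

The generator is first-class, tested code, and its defaults are the study
conditions used throughout the tests: a forward-time birth–death clade from
160 Ma (speciation 0.07, extinction 0.05 /My/lineage — a slowly radiating
marine clade leaving a few dozen preserved taxa), homogeneous-Poisson
preservation at 0.1 finds/My/lineage (FAD = oldest find, LAD = youngest;
unsampled lineages dropped), an 88-character matrix with 3 ordered
characters and 45.3% missing data (the density of a typical published
matrix of this kind), Mk character evolution at 0.02 changes/My (unordered:
symmetric exchange over 2–4 states; ordered: stepwise ±1 over 3–5 states;
root states from the stationary, uniform, distribution), three planted
trait guilds, and AR(1) environments with coefficient 0.5.  Taxa are tip
lineages (bifurcating speciation, no budding): a taxon's true duration runs
from its subtending branch's origin to its tip age, and true standing
diversity counts those intervals so it is directly comparable to taxic
diversity from observed ranges.

Guild means are vertices of a regular simplex with edge length `separation`
(in within-guild SD units), rotated by a fixed orthonormal frame so the
shift spreads over all seven traits.  The spreading is essential: a mean
shift confined to one trait inflates that trait's variance, and per-trait
standardisation would then crush the planted signal while pure-noise traits
kept unit variance.

An optional pulse (`pulse_age`, `pulse_kill`) kills each lineage alive at
that instant with fixed probability — a piecewise extinction spike for
two-phase-extinction experiments.  The planted-pulse recovery experiment
uses a growing clade (0.1/0.04 per My from 100 Ma), dense preservation
(1 find/My), a pulse at 37.5 Ma killing 80%, 5-My bins over (20, 100], and
conditions on at least 10 lineages alive at the pulse.  The bin window ends
before the simulation edge deliberately: observed ranges truncate at the
present, so a surviving clade's extant taxa would otherwise pile spurious
"last appearances" into the youngest bin, exactly as a real compilation
ends at the last well-sampled stage.  Recovery is scored on the per-bin
extinction-count series (the pulse bin attains the maximum).  The
per-lineage rate is structurally unsuitable as the recovery statistic: the
terminal bin of any fully extinct clade reaches 100% by definition, so an
interior pulse killing less than everything can never be the per-lineage
maximum; the pulse bin is instead checked against the 40% per-lineage
threshold that characterises severe extinction phases.

What the generator does not emulate: heterogeneous preservation in time or
space (recovery is homogeneous Poisson, matching the constant-recovery
assumption of the range-extension tests it validates), budding or
anagenetic speciation, character correlation or rate heterogeneity across
branches, measurement error in trait tables, and any causal coupling
between the environmental series and the clade's rates.  Passing tests
therefore demonstrate the estimators' correctness under their own
assumptions, not robustness to these violations.

## Problem sizes and numerical choices

Test problem sizes are chosen to exercise the mathematics at desk scale:
brute-force oracles run on trees of up to 6 tips / 4 states (ancestral
reconstruction, 500 random instances), 4 tips over an age grid
(timescaling), and up to 7 points (Ward); calibration experiments use
10,000 replicates for the correlation type-I error (series length 25) and
Poisson coverage, 500 fits at n = 200 for the GLS recovery, and 200 clades
for the pulse experiment.  Bootstrap defaults are 10,000 replicates in the
library; the analysis drivers use 1,000–2,000 for routine runs.
Eigenvalues are considered positive above a relative tolerance of 1e-10 of
the leading eigenvalue; MPR cost ties use an absolute tolerance of 1e-9;
Ward merge ties are broken by the lexicographically smallest member pair;
bootstrap probabilities are clipped to `[1/(2B), 1 - 1/(2B)]` before the
probit transform.  Degenerate inputs (constant series, zero-variance
traits, bins with fewer than two members, zero-duration branches) are
either defined explicitly above or rejected with a named error rather than
silently handled.
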