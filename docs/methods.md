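# Methods

## The depth model

A nucleus with ploidy *p* carries *p* copies of every autosomal site.
Each copy is captured in a sequenced fragment independently with
probability *s* (the per-copy capture efficiency, typically 0.005–0.05
for snATAC-seq depths of 10³–10⁵ fragments per nucleus), so the number
of fragments covering a site is binomial(*p*, *s*). Two practical
problems — most sites have depth 0, and adjacent sites are correlated
within a read — are removed by observing only the distinct 5′-end
positions of the cell's own fragments. A fragment always covers its own
5′ end, so the observed depth is binomial(*p*, *s*) truncated to ≥ 1.
Per cell, `f[x]` counts observation sites of depth exactly *x*
(FEDECS); the interchange vector is capped at depth 6 (deeper sites
pool into f₆), but moment statistics are always computed from the
exact uncapped tally so binning cannot bias them.

Two conventions matter and are fixed here: coordinates are 0-based
half-open (the 10x fragments dialect, start = 5′ end on the positive
strand); and observation points are **distinct sites**, not per-fragment
records — two fragments sharing a 5′ end contribute one observation of
depth ≥ 2. The package deduplicates identical
(chrom, start, end, barcode) rows on input, treating them as PCR
duplicates.

With T₁ = Σ x f_x, T₂ = Σ x² f_x, the statistic U = T₂/T₁ − 1 has
E[T₂]/E[T₁] − 1 = (p − 1)s exactly, independent of the unknown site
count. U = 0 iff every observed depth is 1.

## Moment-method ploidy inference

Across cells, log U concentrates at log(p − 1) + log s. For robustness
V = log U is winsorized to [2Q₁ − med, 2Q₃ − med], quartiles (linear
interpolation) taken over the cells' log U; cells with U = 0 are
assigned the lower clip bound, the most diploid-leaning value, since
their log is undefined. The shared scale minimises
Σᵢ min_{p∈P} (Vᵢ − log(p−1) − log s)². The objective is piecewise
quadratic in log s, so it is solved by alternating nearest-centre
assignment with the closed-form mean update (1-D k-means with fixed
offsets), multistarted from each candidate ploidy's implied scale —
deterministic, no tolerance beyond a 1e−12 fixed-point criterion.
Assignment ties break toward the smaller ploidy, the conservative
choice with respect to polyploidy claims. The candidate set defaults to
P = {2, 4, 8} (atlas setting) and {2, 4} for CNV work. A fractional
ploidy U/ŝ + 1 is reported but not otherwise used.

## EM mixture inference

The capped counts over (f₂, f₃, f₄) — f₁ dwarfs the others and carries
little shape — are modelled per cell as a multinomial draw with the
cell's own total, from one of |P| unconstrained categorical
distributions. EM runs from a deterministic initialisation (cells split
into |P| quantile groups by their terminal-category fraction) plus two
seeded random restarts; the best converged fit wins. Convergence is a
relative log-likelihood change below 1e−8 within 1,000 iterations; a
component whose weight falls below 1/(10·cells) marks the run failed.
If no restart converges on (f₂, f₃, f₄), the fit is retried on
(f₃, f₄, f₅); failure of both raises an error carrying the trajectories.
Probabilities are floored at 1e−10 against log(0). Components are
mapped to sorted P by the size order of their last-category
probability — more mass at high depth means higher ploidy — which makes
labels invariant to component permutation. Cells with zero counts over
the used categories cannot be scored and are excluded (reported).

## Polyploidy excess across groups

Cells are polyploid when their called ploidy exceeds 2. Counts
aggregated per group × experiment enter a binomial GLM (logit link)
with one indicator per group and sum-to-zero-coded experiment effects,
so each group coefficient is the group's logit proportion at the
average batch; proportion and SE come from the inverse link and the
delta method. Groups with 0 or 100 % polyploids would have divergent
logits; they receive a +0.5/+0.5 continuity adjustment and are flagged.
The background is the first quartile (linear interpolation) of group
estimates — the polyploid rate observable even in diploid cell types —
and each group's excess is a one-sided normal test of
Z = (estimate − background)/SE at level α/n_tests (α = 0.01;
n_tests defaults to the number of groups in the run; fixed values such
as 229 tests can be supplied when combining runs).

## S-phase score

Replication origins (BED input; point origins are interval midpoints)
are flanked by a quarter of the gap to each neighbouring origin, capped
at 50 kb; first/last origins use the cap on their open side. Termini
are the complement within [first − cap, last + cap] per chromosome.
Per cell, U is computed over observation points falling in origin
versus terminus regions (depth still counts all of the cell's
fragments; only the tally is restricted). In G1 cells the two scale
together regardless of ploidy, so an OLS fit of U_ori on U_ter (with
intercept — nothing forces the line through zero) captures the resting
relationship, and its residual is the S-phase score. The fit's R² is
reported and a warning is emitted below 0.8, since a poor terminus fit
means the residual no longer isolates replication signal. The group
test refits with group indicators and experiment covariates (dropped
with a note when only one experiment is present), takes the
⌈n/4⌉-ranked group coefficient as baseline, and tests each group's
departure two-sided via a linear contrast. Because the baseline is a
selected order statistic, the null rejection rate runs slightly above
nominal (≈4–8 % at the 5 % level in our calibration simulations).

## CNV detection

U is computed per cell for every 20 Mb window (terminal remainders
under 10 Mb merge into the preceding window); windows with fewer than
50 observation points (default floor) are missing. A Huber robust
regression (tuning constant 1.345, coefficient convergence 1e−8) of
the diploid cells' U on a per-window accessibility covariate gives a
fitted value varying only by window; U′ = U/fitted removes both the
accessibility effect and the capture scale, so U′ ≈ U/s. Without a
covariate the fit is intercept-only (a pure rescaling) and a warning is
emitted. With U′_cell the cell's median over non-missing windows,
p̃ = 2(U′_cw + 1)/(U′_cell + 1) is the window's copy number as if the
cell were diploid: gain at p̃ ≥ 3, loss at p̃ ≤ 1.

Shared CNVs are blocks in the 0/1 gain (or loss) flag matrix. For
every within-chromosome run of ≥ 2 consecutive windows, cells are
ranked by their proportion of flags inside the series and every top-k
prefix is scored by ΔBIC = −2(ll₂ − ll₁) + log N, where ll₁ is the
single-rate Bernoulli likelihood of the whole matrix, ll₂ the two-block
likelihood (one rate inside the cells × series block, one outside),
and N the number of non-missing entries (missing entries are excluded
from likelihoods and the penalty). At fixed subset size the two-block
log-likelihood is convex in the inside-flag count, so descending- and
ascending-proportion prefixes attain the optimum over *all* subsets of
that size when the series has no missing entries; with missing entries
the prefix scan is a heuristic.

Raw ΔBIC < 0 alone is anticonservative: the block's cell subset and
window span are themselves optimised over roughly
#series × C(cells, k) configurations, and unpenalised selection makes
spurious blocks (e.g. a single cell with flags at two adjacent windows)
score negative. The greedy selector therefore accepts a candidate only
if (i) its raw ΔBIC is negative, (ii) the discounted score
ΔBIC + 2[ln(#series) + ln C(cells, k)] is still negative — a Bayes
factor with a uniform prior over block configurations, (iii) it has at
least 3 member cells, and (iv) every window of the series is
individually enriched in the member cells over the outside rate, so a
lone aberrant window cannot ride in on a neutral neighbour. Gains and
losses are scanned independently; accepted segments of one kind never
overlap in windows; the raw ΔBIC remains the reported statistic.

## Simulator

The generator realises the site model literally: observation sites are
pre-placed on a synthetic genome at fixed spacing
max(2·fragment length, genome/sites) — at least twice the fragment
length, so no fragment reaches the next site and each site's observed
depth equals its own draw. Depths come from a single uniform stream per
cell through the inverse CDF, making the stream independent of the
local copy number; fragment lengths jitter within [L, 2L) and
intra-cell collisions at a site are redrawn, so a cell's fragments are
never coordinate-identical. Two modes:

* truncated (default): depths ~ binomial(p, s) | ≥ 1 at exactly
  `n_sites` sites, which makes FEDECS computed from simulated fragments
  reproduce direct FEDECS simulation draw-for-draw;
* unconditioned: depths ~ binomial(p, s) on the shared grid, zeros
  unobserved — the mode for in-silico merging, where pooling k diploids
  must give binomial(2k, s)-truncated depths and hence
  E[U] = (2k − 1)s. For a single nucleus the observed depth marginal is
  identical in both modes.

Merging pools each group's fragments under a new barcode;
coordinate-identical fragments across members collapse, mirroring the
real assay's PCR-duplicate ambiguity (made negligible by length
jitter). The default merge design draws 7 nuclei repeatedly into
groups of 1, 2 and 4. CNV events add a copy delta inside a genomic
interval for the first ⌈fraction · cells⌉ cells.

Default study conditions used throughout the tests and the acceptance
script: s = 0.02, 5 × 10⁴ sites per cell and 300 cells per ploidy
class for mixtures (2 × 10⁴ sites and 210 nuclei for merge cohorts —
sizes chosen so that per-cell U standard errors are far smaller than
the cluster spacing, matching the regime of a 10³–10⁵-fragment
nucleus); CNV calibration uses 100 cells × 20 windows with background
flag rate 0.02 and an implanted 40-cell × 4-window block at rate 0.9.

What the simulator does *not* emulate: peak structure and Tn5 insertion
bias, chromatin-state-dependent capture heterogeneity (beyond the
optional per-window covariate), doublets, and mappability artifacts.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to every property of real chromatin
data — the EM route exists precisely because real data bend the
uniform-capture assumption.

## Degenerate inputs and numerical choices

Empty depth tallies, all-zero U, fewer than 4 cells for quartiles,
fewer than 3 cells for the S-phase regression, single-origin
chromosomes, unsorted origins, non-positive window sizes, and empty
diploid reference sets all raise errors rather than guessing.
Chromosomes missing from a repeat mask are kept with a warning.
Windows whose fitted accessibility is non-positive become missing with
a warning. Quantiles use linear interpolation throughout; assignment
ties prefer smaller ploidies; greedy CNV ties order by
(ΔBIC, chromosome, start) for reproducibility.

## Known limitations

Sex chromosomes are out of scope (the model assumes autosomal copy
number). The moment method assumes one shared s across cells of an
experiment; batches with different capture efficiency should be
processed separately or classified with the EM route. CNV resolution
is bounded by the fragment count per window (hence the 20 Mb default),
and the caller reports shared segments, not per-cell events. Discrete
cell-cycle phase assignment from the fractional ploidy or the S-phase
score is deliberately not attempted.
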