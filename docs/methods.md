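# Methods

This note records the statistical model behind `spatialcci`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data can and cannot tell you about real tissue.

## Spatial tendency of an interaction

A gene's spatial expression distribution places probability mass at every
spot where it is detected, proportional to its (normalized) expression. For
a subunit complex the per-spot mass is the elementwise minimum over
subunits: a complex cannot be present where any subunit is absent. Zero-mass
spots are dropped and weights renormalized to one.

The separation between ligand distribution L (m support spots) and receptor
distribution R (n support spots) is the optimal-transport cost under the
Euclidean ground metric D in slide units,

    W(L, R) = min_{gamma in Gamma(L, R)} <gamma, D>,

solved in its entropic-regularized form by the Sinkhorn algorithm and
symmetrized, `W_LR = (W(L,R) + W(R,L)) / 2`, because finite-iteration
Sinkhorn results depend slightly on argument order. `W_LR` is invariant
under rigid motions of the slide and scales linearly with slide units.

The permutation null re-assigns the ligand's and the receptor's full
per-spot value vectors to independently permuted spot positions — all slide
spots participate, not only the originally expressed subset, which is the
most literal reading of "permute the spot positions" and keeps the null
free of support-dependent artifacts. Both marginals' weights are unchanged;
only geometry is randomized. From `n_perm` replicates (default 1000),

    d_ratio = d_real / mean(d_simulation),
    p_left  = (#{d_sim <= d_real} + 1) / (n_perm + 1),
    p_right = (#{d_sim >= d_real} + 1) / (n_perm + 1).

The add-one P-value estimator guarantees p in (0, 1] and is standard for
permutation tests; `p < 0.01` therefore requires `n_perm >= 100`. Under the
null construction E[d_ratio] = 1 and the P-values are uniform; both are
verified empirically by the test-suite (KS test over 200 replicates).

Classification intersects two ranked top-fractions (default 10%): short
candidates are in the smallest 10% by `d_ratio` *and* by `p_left`; long
candidates in the largest 10% by `d_ratio` and smallest by `p_right`;
candidates pass only with the relevant one-sided `p < alpha` (default
0.01). The wording of the selection rule admits either an intersection or a
composite rank; we default to the intersection and expose
`strategy="composite"` (sum of the two ranks) as an alternative. Ties at
the boundary break by P-value then interaction name, so results are
reproducible. The top fraction is a parameter because sparse slides may
need a more permissive cutoff (e.g. 15%) to yield enough classified
interactions for scoring.

### Normalization

Counts are library-size scaled to the median spot total and log1p
transformed before distributions are built. Variance-stabilizing
Pearson-residual schemes are a reasonable alternative; the
`normalize_counts(transform=...)` hook accepts any matrix-to-matrix
function, and negative values produced by such schemes are clamped to zero
because distribution mass must be non-negative.

### Numerical implementation of the transport cost

The Sinkhorn solver runs entirely in the log domain, so a regularization
far below the cost scale (the default `reg = 0.001` with slide diameters
near 1) cannot underflow the Gibbs kernel. The regularization is annealed:
iterations start at ~max(D)/4 and halve stage by stage down to `reg`,
warm-starting the dual potentials (epsilon scaling). Before the cost is
read off, the plan is projected onto the exact marginals (row/column
scaling plus a rank-one correction), so the reported value is always the
cost of a *feasible* plan even when iterations stop early. Against the
exact linear program (scipy HiGHS) on random instances the symmetrized cost
agrees to well under 1% on the accurate single-instance path.

The permutation null is solved in batch: all replicates share the same
marginal weights and differ only in geometry, so the cost tensors are
stacked and iterated together in float32 with a capped iteration budget
(max 150 final-stage iterations, marginal tolerance 5e-3). The feasibility
projection bounds the per-replicate error at roughly 1-3%; crucially,
`d_real` inside the tendency pipeline is computed through the *same*
batched settings, so solver bias cancels out of `d_ratio` and the P-values
(the calibration tests confirm this). Degenerate inputs are handled
explicitly: coincident support points give cost 0, a one-point-to-one-point
plan is exact by construction, and an all-zero expression vector raises a
degenerate-distribution error rather than returning a silent 0.

## Near and far cell-type pairs

Spots are annotated by argmax deconvolution proportion (ties to the
lexicographically first type; all-zero rows are an error naming the spots).
The distance between cell types a and b is

    ct_distance = ( mean_i min_j d(a_i, b_j) + mean_j min_i d(b_j, a_i) ) / 2,

symmetric and rigid-motion invariant. Pair distances are clustered with
k = 3 and labeled near / medium / far by ascending cluster mean. In one
dimension the optimal k-means is a contiguous partition of the sorted
values, which dynamic programming finds exactly; we use the exact DP up to
50 pairs (covering any realistic number of cell types) and seeded 10-restart
k-means beyond. Fewer than 3 pairs fall back to a warned tertile split, and
an all-equidistant configuration labels everything medium — both situations
indicate the slide cannot support a near/far contrast.

## Distance enrichment score

The expected short list ranks all short-range interactions by (`d_ratio`
asc, `p_left` asc, name); the long list by (`d_ratio` desc, `p_right` asc,
name). Scoring a tool's observed set S against a list L of length `ns` with
`nm = |L ∩ S|` matches walks the list accumulating

    +(1 - p_j) / sum_{matches}(1 - p)   if entry j in S,
    -1 / (ns - nm)                      otherwise,

and DES is the maximum of the running sum (never below 0, since the last
position always returns to 0; never above 1, the total match mass). Edge
cases are defined rather than left to division: `nm = 0` gives DES 0 (no
matched mass) and `nm = ns` gives DES 1 (no unmatched entries exist). The
weight is the expected interaction's one-sided permutation P-value — left
for short, right for long. If every matched P-value is exactly 1 the match
weights degenerate to equal steps.

Predictions for an unordered pair pool both directions, because the pair
distance is symmetric and cannot attribute direction. Medium pairs and
medium-range interactions never enter the DES. A tool's summary is the
unweighted mean over scored pairs; ranks are competition-free (ties share
the average position), and cross-dataset summaries average per-dataset
ranks.

## Consensus metrics

The consensus reference holds interactions predicted for the same *ordered*
(source, target) pair by at least `min_tools` (default 3) distinct tools;
duplicates within one tool count once. Precision / recall / F1 are computed
per pair and macro-averaged over pairs with a non-empty reference (the
primary report); pooled micro totals are emitted alongside because the two
can disagree when pair sizes are skewed. The LR-product baseline scores
each database interaction per ordered pair by mean ligand expression in the
sender times mean receptor expression in the receiver (complexes: minimum
subunit mean per side) and keeps the top 10 positive scores per direction.

## Simulator

The simulation plants known interactions into paired scRNA-seq/ST data in
three steps. (1) Four cell types containing at least one near and one far
pair are selected (so both DES sides are exercised); each retained spot
draws a uniform-integer 2-5 cells of its own type, sampled without
replacement until a type's pool is exhausted (then with replacement, and the
type is flagged in `resampled_types`); spot expression is the sum of its
cells and coordinates are untouched. (2) Per near/far pair, 30 interactions
are drawn with globally disjoint genes — so restoring one plant can never
corrupt another — given a random direction, and overexpressed: the planted
gene's counts in the target cell type are replaced by counts resampled with
replacement from a donor gene in that type's top-5% mean-expression pool.
Resampling real counts preserves realistic dispersion while guaranteeing
signal; a donor must exceed twice the planted gene's current mean (else the
highest-mean gene is used), so planted means strictly increase. (3) The
full tendency pipeline is re-run on the planted slide; plants classified
short-range in near pairs or long-range in far pairs are kept, all others
have their pre-plant counts restored in both modalities, and spot sums are
recomputed from the final cell matrix. TF/target overexpression for kept
interactions runs only when a regulatory table is supplied, otherwise it is
skipped with a log line.

How many plants survive step 3 is a *consequence*, not a target: the top
10% cutoff admits only ~`0.1 x n_covered` interactions per side, so of 30
planted per pair roughly a third survive (about 10 per pair on the default
fixture), and the realized count is reported in the truth table.

### The synthetic tissue fixture

`make_fixture` builds the template the simulation draws from, emulating the
two spatial regimes of real tissue: the first two cell types interleave on
a checkerboard inside one domain — their cells are in mutual contact, so a
ligand in one type and receptor in the other genuinely colocalize (the near
pair) — while remaining types occupy vertical bands whose uneven spacing
(0.5 and 1.0 on a unit axis against the mixed domain at 0) produces medium
and far pairs under k-means. Counts are negative binomial (dispersion 2)
with per-type marker genes at mean 10 — these markers double as the
overexpression donor pool — and all other genes, including the dedicated
ligand/receptor gene pairs of the synthetic database, at baseline mean
0.05 per cell (spot-level detection ~15%, above the 10% coverage filter).
The synthetic database holds 150 interactions, 10 of them with two-subunit
receptors.

Slide and matrix sizes (96 spots, 200 cells per type, ~360 genes) are
chosen so the full pipeline — including the 100-permutation transport null
for every covered interaction — completes in minutes on one core; they are
the package's default desk-scale study conditions, and everything scales up
by parameter.

### What passing tests do and do not show

The fixture has sharply segregated or perfectly mixed domains, independent
negative-binomial counts, no spatial expression gradients within a domain,
no doublets or segmentation noise, and single-type spots under argmax
annotation. Passing the planted-recovery and calibration tests therefore
shows the statistics are correct and self-consistent under the stated
model; it does not certify performance on real slides, where mixed spots,
boundary effects (a cell type whose *edge* touches another while its bulk
is distant), and expression gradients blur the short/long dichotomy — the
global pair distance is known to misclassify boundary contacts, and
mini-clustering of large domains would be the natural extension.

## Known limitations

- The entropic solver's batched path trades ~1-3% cost accuracy for two
  orders of magnitude in speed; absolute `d_real` values quoted from the
  pipeline carry that tolerance (the ratio statistics do not, by bias
  cancellation).
- The DES compares sets, ignoring prediction scores beyond membership; two
  tools predicting the same set with different confidence rank equally.
- Consensus F1 measures agreement with the tool ensemble, not truth; a tool
  can be penalized for being right alone.
- The simulator's overexpression mechanism resamples counts gene-wise and
  ignores gene-gene correlation within cells.
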