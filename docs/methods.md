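# Methods

## Dated trees and the covariance structure

All statistics operate on a rooted, binary, ultrametric phylogeny with
branch lengths in millions of years; ages run backwards from the present
(tips at 0, root at `root_age` mya). Ultrametricity is checked on
root-to-tip depths with a relative tolerance of 1e-6 (overridable) —
dated trees emitted by MCMC samplers carry rounding noise at about that
scale. Polytomies are rejected by default because the contrast recursion
requires a binary tree; an opt-in flag resolves them deterministically
(children ordered by smallest descendant tip label) into zero-length
bifurcations. Zero-length terminal branches are allowed but trigger a
warning, since they make contrast variances degenerate.

The phylogenetic covariance matrix C (shared root-to-MRCA path lengths)
is the single object the signal statistics need. Pruning a tree to a
species subset collapses unifurcations by summing branch lengths, which
preserves every pairwise shared depth — so the covariance of a pruned
tree is exactly the corresponding submatrix of the full one (tested).
Linear solves use a Cholesky factorization of C rather than explicit
inversion; no jitter is added silently (a singular C raises with a hint).

## Phylogenetic signal

**Blomberg's K** is the observed ratio of among-species variance to
phylogenetically corrected variance, divided by its Brownian-motion
expectation; on a star phylogeny (C proportional to the identity) the two
ratios coincide and K = 1 identically. The permutation test shuffles
trait values across tips; the P-value is one-sided in the
signal-is-large direction with add-one smoothing,
P = (1 + #{K_perm ≥ K_obs})/(1 + B), so P ≥ 1/(B+1). Permutations are
evaluated through one vectorized matrix product, and the observed vector
is pushed through the same product as the permutations: BLAS gemm and
gemv round differently at machine precision, and evaluating them through
different code paths would break exact ties (a constant trait must tie
with every permutation of itself).

**Pagel's λ** multiplies the off-diagonal entries of C by λ ∈ [0, 1].
For fixed λ the mean and rate have closed-form ML estimates, giving the
profile log-likelihood
−½[n·ln(2πσ̂²) + ln det C_λ + n]; the scalar λ is then maximized by
bounded search (tolerance 1e-8) with both boundaries checked explicitly,
since λ̂ = 0 and λ̂ = 1 are legitimate estimates. The reported P is a
likelihood-ratio test of λ̂ against λ = 0 on one degree of freedom, with
no boundary mixture correction — the convention of the standard
comparative-methods tools, conservative when the truth sits at the
boundary. λ is restricted to [0, 1]; values above 1 are not meaningful
for ultrametric trees. Traits are analyzed on the scale given in the
input table; a log10 flag is available for body size.

Implementation checks: K, λ̂, the profile log-likelihoods, the LR
P-value and all standardized contrasts were verified against ape 5.8 /
phytools 2.5 (`phylosig`, `pic`) on a frozen 8-tip fixture; the profile
likelihood is also tested against direct multivariate-normal density
evaluation on random instances (agreement to 1e-6).

## Contrasts and shift detection

Contrasts follow the standard pruning recursion: at a node with daughter
values x_i, x_j on variance-adjusted branch lengths v_i, v_j, the raw
contrast is x_i − x_j, standardized by √(v_i + v_j); the node carries the
precision-weighted average value, and its parent branch is lengthened by
v_i·v_j/(v_i + v_j). Because node values are weighted averages, every
standardized contrast is a fixed linear combination of the tip vector;
the coefficient matrix is built once, and both the observed contrasts and
the full permutation null reduce to matrix products.

"Shift detection" asks, per node, whether the observed |standardized
contrast| is extreme against the distribution obtained by permuting trait
values across tips (two-sided empirical P, add-one smoothing). This is an
interpretation of running contrasts with many random replicates: the
permutation null is the natural well-defined reading of flagging nodes
whose divergence is larger or smaller than expected. Two modes are
provided — per-node (each node against its own permutation distribution;
the default) and pooled (each node against all nodes' permuted
contrasts) — because the choice between them is genuinely open. No
multiple-testing correction is applied by default, matching the
exploratory use of shift arrows on published trees; Benjamini–Hochberg
is available by flag.

One consequence worth stating plainly: a mean shift applied to every tip
of a clade leaves the contrast at that clade's crown node unchanged (both
daughters shift together) and instead produces the extreme contrast at
the node joining the shifted clade to its sister. Power simulations and
the shift-time annotation therefore look at that joining node; on a
published figure the arrow sits at the divergence where the daughters
differ, which is the same convention.

Zero-length daughter branches get machine-epsilon × root_age added, with
a warning; a node whose daughters both have zero variance raises.

## Trophic-level scoring

Within one habitat (one community), species mean δ¹⁵N is normalized by
the habitat baseline and anchored at the community minimum (the lichen-
feeding specialists): with d = y − min(y), the integer group is
min(3, ⌊d/3.4⌋) and the decimal is the within-group fractional distance
(d − 3.4·group)/3.4 capped at 0.99, so scores are monotone in δ¹⁵N, equal
for ties, and confined to [0.0, 3.99]; anything beyond four group widths
is clamped into the predator/scavenger group. The 3.4 ‰ spacing is the
canonical per-trophic-level ¹⁵N enrichment. The continuous decimal is the
default because it is order-preserving and reproducible from the values
alone; a rank-based decimal (dense rank within group scaled to [0, 0.99])
is available by flag since the "relative position within the level"
wording admits both. Species measured in several habitats receive the
arithmetic mean of their per-habitat scores, with a flag when the
habitats disagree on the integer group. δ¹³C is normalized and carried
through for reporting (it separates carbon sources) but never enters the
score. Normalized tables are tagged so normalizing twice — which would
silently shift every score — raises instead.

## Branching times and event overlay

Internal-node ages are binned into half-open [t, t + 5 my) intervals from
the present to just past the root; counts always sum to n − 1.
`interval_fraction` counts ages in [t_young, t_old) and is additive over
disjoint intervals. The event overlay is a descriptive device, not a
test: branchings in the half-open window [mid − 10, mid + 10) my around
each event midpoint are rescaled to a per-bin rate and labelled "gap"
below the 25th percentile of bin counts, "rise" above the 75th, and
"typical" otherwise. Interval-dated events (e.g. a stage given as
303–307 mya) enter via their midpoint. Windows are half-open like the
bins so that a perfectly flat profile yields the same rate at every
midpoint and labels every event "typical". No formal correlation test
between events and gaps is attempted.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analyses assume,
at the scale of the motivating study system: Yule trees of ~110 tips with
a ~400-my root (lineages split after exponential waits, the splitting
lineage chosen uniformly, an exponential tail appended so terminal
branches are never zero, then branch lengths rescaled to the target root
age — a conditioning shortcut adequate for test topologies); Brownian
traits as per-branch Gaussian increments with variance σ²·branch length;
λ-model traits as multivariate normal draws with covariance
σ²·C_λ; clade shifts as a constant mean offset on all tips of a clade;
and isotope compilations of 70 species across 4 habitats, with per-
habitat baselines, δ¹⁵N = baseline + 3.4 × true level + Gaussian noise
(sd 0.25 ‰ by default, homoscedastic — the simplest structure consistent
with analyzing species means), and membership of each species in a random
subset of habitats. The bundled morphology table evolves log10 body
length (ancestor 300 µm) and log10 length/width ratio (ancestor 1.8) by
Brownian motion, keeping sizes positive and rates proportional.

Passing tests on these data show the estimators and the scoring scheme
are correct under their own assumptions. They do not show robustness to
what real compilations contain: measurement error in traits, non-Brownian
evolution (selection, rate shifts), non-ultrametric dating error,
heteroscedastic or non-Gaussian isotope noise, baselines estimated with
error, or taxonomic name mismatches beyond exact-string matching.

All generators are pure functions of (parameters, seed); a single
pipeline seed expands into independent per-stage substreams
(`numpy.random.SeedSequence`), so partial reruns and full reruns agree
bit for bit.

## Problem sizes and defaults

Signal and shift tests default to 9999 permutations (α = 0.05). The
validation suite uses 100–200-tip trees, 500 simulations × 999
permutations for type-I calibration, 50 replicates per λ for recovery,
and 100/200 replicates for shift power and false-flag rates — sizes at
which Monte-Carlo error is comfortably inside the asserted bands (e.g.
binomial SE ≈ 0.01 at 500 sims for a 0.05 rejection rate, band
0.03–0.07). The false-flag band for per-node shift tests is 0.025–0.075,
slightly wider than the K band because the per-node fractions are
correlated across nodes within a tree.

## Known limitations

- Only the λ transform is implemented; no Ornstein–Uhlenbeck or
  multi-rate models, no measurement-error extensions of K/λ.
- The LR test for λ is conservative at the boundary (no 50:50 mixture).
- The permutation null for shift detection assumes tip exchangeability
  under the no-shift hypothesis; under strong Brownian correlation the
  per-node false-flag rate tracks α on average but is not exact per node.
- Trophic scores depend on the community minimum; a community missing
  its low-δ¹⁵N specialists will shift all its scores down.
- Trees must be binary after optional polytomy resolution; NEXUS input
  is not supported (Newick only).
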