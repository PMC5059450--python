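# Methods

This note records the models, conventions and design choices behind
`paleodiv`, in the order the pipeline runs them: supertree assembly,
fossil time-scaling, birth–death shift inference, and climate
correlation, plus the synthetic-data generators that every validation
experiment rests on.

## Coordinate conventions

Ages are in Ma before present; the present is 0 and ages increase into
the past. Branch durations are in Myr. All rate and proxy grids use a
uniform 0.1 Myr step on this axis. A branch *crosses* an age `a` when
`child.age <= a < parent.age` (half-open, child-inclusive), which makes
counting at node ages unambiguous: moving toward the present past a
bifurcation, the lineage count steps up by exactly one.

## Supertree assembly (MRP)

Source trees are encoded by Baum–Ragan matrix representation: one
binary character per informative internal node (root excluded — it is
uninformative given the all-zero hypothetical outgroup `MRP_Outgroup`),
with 1 for taxa subtended by the node, 0 for the source tree's other
taxa, and `?` for taxa absent from that source tree. A dataset is
usable when the graph joining source trees that share at least two taxa
is connected.

Parsimony lengths treat `?` as a free state. Binary trees are scored
with a bit-parallel Fitch pass (all characters packed into Python
integers; intersection/union per node); polytomies go through
Hartigan's vote-counting generalization, which is exact on
multifurcations. Both paths are validated against exhaustive
enumeration of all internal-state assignments on small inputs.

Search comes in two forms. The exhaustive search enumerates every
rooted binary topology over the matrix's real taxa (the outgroup is
attached above the root, which both roots the tree and contributes its
all-zero row to the score) and returns all ties at minimum length; it
refuses more than 9 taxa. The heuristic search uses random
taxon-addition starting trees refined by NNI hill-climbing, repeated
over replicates, followed by a plateau sweep that collects equal-score
NNI neighbours (capped) so that strict consensus sees the tie set. NNI
rather than TBR keeps the neighbourhood small at desk scale; the
exhaustive search is the oracle that bounds what the heuristic can
miss.

Consensus (strict and majority) is computed from rooted clade
("cluster") counts. Conflict among tied trees can instead be pruned
with a rooted maximum agreement subtree: an exact dynamic program over
node pairs for two binary trees, with ties broken toward the
lexicographically smallest taxon set so the operation is deterministic
and symmetric. Multi-tree pruning folds the pairwise operation over the
input in order; this is a heuristic, not an exact multi-tree MAST.
Note the rooted semantics: the conflicting quartets `((A,B),(C,D))` vs
`((A,C),(B,D))` share no rooted 3-taxon restriction, so their rooted
agreement subtree has 2 tips (the unrooted answer would be 3).

## Fossil time-scaling (the 'equal' rule)

Calibrations are fossil first occurrences: hard *minimum* ages attached
to the crown (MRCA) or stem (parent of MRCA) of a named clade. When two
calibrations resolve to one node the older age wins. Scaling then
proceeds in two passes:

1. a postorder pass computes each node's hard floor — the maximum of
   its own calibration and every child's floor plus the minimum branch
   length `min_bl` (default 0.1 Myr);
2. a preorder pass fixes calibrated nodes at their floors and, for each
   maximal chain of uncalibrated nodes between a dated (or root)
   ancestor and the descendant anchor with the tightest floor, divides
   the free interval equally among the chain's branches, clamped from
   below by each node's floor.

The root sits at its own floor, i.e. it extends as far back as its
constraints require and no further. Consequences worth noting: every
branch ends up at least `min_bl` long; a parent and child both
calibrated at the same age resolve to child at the age and parent
`min_bl` older (with a warning); and a fully calibrated tree whose true
branches are all at least `min_bl` long is returned unchanged. The
equal-division rule is recomputed per node during descent, which
reproduces exact k-way equal splits along chains.

For robustness reruns, a chosen fraction of calibration entries
(⌈f·n⌉, sampled without replacement) is re-attached to the parent of
its resolved node or to a uniformly chosen child — a fair coin decides
the direction, except at the root where only children are available.
Because a tip cannot carry a positive minimum age, only internal
children are eligible; a node with no internal child sends the entry to
its parent. Ages are never changed by perturbation.

## Birth–death shift model

The diversification model is a compound-Poisson rate-shift process on
the fixed dated tree: a root regime (λ, μ) plus shift events, each
placed at an age on a branch and starting a new constant-rate regime
inherited by all descendants until overridden. Regimes are constant in
time. This is the principal modelling simplification relative to
frameworks that let λ decay within a regime; it keeps the likelihood in
closed form so an independent ODE integration can verify it, and the
correlation stage consumes only rate-through-time curves. The price is
discussed under *Limitations*.

The likelihood is the standard reconstructed-process density with
per-tip sampling fractions: extinction probability `E` and density `D`
propagate from the tips (E = 1 − f, D = f) to the root through

    E' = μ − (λ+μ)E + λE²,   D' = −(λ+μ)D + 2λED,

solved per constant-rate segment via the logistic substitution
u = 1 − E (u' = ru − λu², r = λ − μ), giving

    u₁ = r·u₀·e^{rΔ} / (r + λ·u₀·(e^{rΔ} − 1)),
    log D₁ − log D₀ = 2·log(u₁/u₀) − rΔ,

with a series-safe branch for |r| → 0. Internal nodes multiply the two
child densities and the λ governing the node's age; the root is
conditioned on survival of both descendant lineages by dividing by
(1 − E_root)². With μ = 0 and f = 1 this reduces exactly to the Yule
log-likelihood Σ log λ − λ·(total branch time).

The posterior over shift configurations is sampled by reversible-jump
MCMC. Moves: multiplicative (log-scale) updates of a regime's λ or μ;
add a shift (branch ∝ duration, age uniform on the branch, rates drawn
from their priors — with prior-draw proposals the dimension-jump
Hastings ratio reduces to the Poisson ratio γ/(K+1)); delete a
uniformly chosen shift; relocate a shift (symmetric under the
uniform-on-tree density). Priors: K ~ Poisson(γ), γ default 1 per tree;
λ and μ exponential with means set from the tree's pure-birth point
estimate ln(n)/root-age (and half of it for μ). Optional Metropolis
coupling runs a β-ladder (βᵢ = 1/(1+0.2i)) with periodic adjacent-chain
swap proposals; only the cold chain is sampled. Shifts are disallowed
on the (zero-length) root branch: the root regime plays that role. The
sampler's dimension mechanics are validated by prior recovery (with the
likelihood disabled, the sampled shift count is Poisson by chi-square).

Branch-level support is summarized as marginal shift probabilities with
a Bayes factor against the Poisson-process prior probability
1 − exp(−γ·branch-duration/tree-length) of at least one shift on that
branch; branches subtending fewer than a minimum clade size (default 5
tips) are excluded from the report, and ties rank older branches first.

Rate-through-time curves sample the mean of λ over the clade's branches
crossing each 0.1 Myr grid age; the grid runs from just below the clade
origin (where at least the two crown branches cross) down to 0. The
curve of a posterior is the pointwise mean of per-sample curves.

## Climate correlation

The benthic δ¹⁸O record rises as the climate cools, so the series is
negated into a warmth-increasing temperature proxy before correlation;
a coefficient of −1 then reads "speciation faster when cooler" and +1
"faster when warmer". Processing: a centred running mean (default 5
points; a running-median alternative is available, since "Tukey
smoothing" classically means running medians — the running mean is the
default here), then linear interpolation onto the 0.1 Myr grid with no
extrapolation ever; at the ends of the series the smoothing window
truncates to the available points.

Each posterior rate curve is correlated with the proxy over the overlap
of the two grids, once with Pearson's r and once with the detrended
cross-correlation coefficient ρ_DCCA(s): both series are integrated
into mean-centred profiles; every overlapping window of s+1 profile
points is linearly detrended; ρ is the mean residual cross-product over
windows normalized by the two detrended-fluctuation amplitudes
(Cauchy–Schwarz guarantees ρ ∈ [−1, 1]). The default box size is
s = ⌊N/4⌋. The scale matters: at small s the within-window detrending
removes slow, trend-like covariation entirely, so a relationship that
lives at the trend scale is only visible for s of order N/4 and above.

The per-curve coefficients are summarized by a two-sided one-sample
t-test of the mean against zero. Posterior draws are not independent,
so the nominal sample size overstates the information content; the
output carries an explicit note to that effect. Zero-variance curves
(e.g. a zero-shift posterior draw, whose rate curve is exactly
constant) have no defined correlation; they are excluded from the
coefficient set and counted separately rather than silently scored 0.

## Synthetic data

`synthgen` produces every input with known ground truth.

* **Birth–death trees**: forward Gillespie simulation from one lineage,
  stopping at a fixed crown-to-present span or at a tip count (the
  present is then placed uniformly within the interval over which the
  count holds, so pendant branches have positive length). Extinct
  lineages are pruned, tips are subsampled by a detection probability
  f, and total extinction triggers a bounded retry. An optional shift
  plan applies new regimes to one random surviving lineage at given
  ages; the returned ground truth maps each shift to its surviving tip
  set.
* **Isotope-like series**: stationary AR(1) on the 0.1 Myr grid,
  optionally with a linear cooling trend (value rising toward the
  present), mimicking the long-term drift plus short-lag
  autocorrelation of the real record.
* **Coupled histories** share the rate law λ = exp(a + b·proxy) in two
  modes. *Continuous*: every lineage's instantaneous rate tracks the
  proxy (thinning algorithm); the signal is synchronous and diffuse.
  *Episodic*: each lineage's rate is constant between Poisson regime
  renewals (default 0.03/lineage/Myr); a renewal re-reads the proxy at
  that moment. Episodic histories carry their realized renewals as
  ground truth. The episodic mode exists because a compound-Poisson
  clade-shift model can only represent clade-structured rate variation:
  on a tree whose *every* lineage changed rate synchronously, the
  correct description needs one shift per crossing branch, and the
  single-shift marginal likelihood gains are near zero even when the
  jointly painted configuration is decisively better — so no
  incremental sampler reaches it, and part of a time-increasing rate is
  absorbed by extinction instead (the pull of the present). This is a
  documented blindness of clade-painting models to diffuse temporal
  signals, not an implementation artefact; the end-to-end sign-recovery
  experiment therefore couples the climate to episodic clade regimes,
  which is also how the real analysis's signal is structured (discrete
  shifts in particular clades).
* **Decompositions and fossils**: random induced subtrees
  (rejection-sampled until the two-shared-taxa overlap graph is
  connected) emulate overlapping source trees; fossil-like calibrations
  draw internal nodes and report age·(1−|ε|), ε ~ N(0, sd), so every
  calibration is a valid minimum.

What the generators do *not* emulate: taxonomic name noise, rogue taxa,
character conflict beyond topology subsampling, fractional (long-
memory) noise in the proxy, and diversity-dependence. Green tests
therefore show that the pipeline's inference chain is internally
correct and recovers structured signals of realistic size — not that
the real data's noise sources are handled.

## Validation experiments and problem sizes

The acceptance script and the slow end of the test suite run the same
experiments (`paleodiv.experiments`), at sizes chosen to complete in
minutes on one core:

* heuristic parsimony vs full enumeration on 100 random 5–7-taxon
  matrices;
* supertree round trip on a 32-taxon model tree decomposed into 10
  overlapping 22-tip source trees, resampled until the sources cover
  all taxa and witness every grouping (without that property several
  most-parsimonious trees tie and no method could single out the
  model);
* likelihood agreement with the ODE oracle on 50 random trees (≤50
  tips, random λ, μ, f) at 1e-6;
* constant-rate recovery on 20 pure-birth trees of 100 tips (20,000
  generations each): 95% credible-interval coverage of λ and the
  posterior shift-count mode;
* detection of a true 5× speciation shift on a ≥20-tip clade of a
  ~200-tip tree, requiring the true branch to rank first by Bayes
  factor — the instance is screened on data-level identifiability
  (shifted-branch length, shift position away from the branch ends, an
  informative sibling subtree);
* end-to-end sign recovery under episodic climate coupling with
  b = ±2, Pearson and DCCA (s = N/4), pooling the coefficient
  distributions of three replicate histories (single histories can
  flip sign through unlucky clade realizations). Each history must
  carry a sparse, sizeable clade signal (2–12 surviving renewals,
  at least two renewed clades of ≥20 tips); the record trends toward
  the coupling's rate-increasing direction — cooling for b < 0,
  warming for b > 0, exact mirrors — because a clade whose coupling
  opposes the trend only ever slows down, and a slowed clade stays
  small and leaves no recoverable imprint. Inference runs under a
  tight extinction prior (mean λ-guess/50): the generator is
  pure-birth by construction, and with extinction free a mirror
  solution (fast baseline + extinction + slow shifts on unrenewed
  clades) ties with the truth and can invert the recovered curves;
* DCCA exactness (±1 identities to 1e-10, direct-summation oracle
  agreement, null AR(1) mean |ρ| < 0.1);
* 'equal' scaling invariants over 1,000 random tree/calibration draws
  and the calibration-perturbation contract at fractions
  0/0.10/0.15/0.20.

## Numerical choices

* Logistic closed form with a dedicated |r| < 1e-12 branch; `u₁` is
  clamped into (0, 1] with 1e-9 tolerance (bare floating-point round-up
  past 1 would otherwise be misread as an invalid state) and exponent
  arguments are capped at 700 to avoid overflow.
* Non-finite likelihoods reject the proposal rather than abort the
  chain; initialization redraws from the prior up to 100 times.
* MCMC per-stage sub-seeds are derived as SHA-256 of
  `"{global_seed}:{stage}"` reduced mod 2³¹, so adding a stage never
  perturbs another stage's stream and every generator stays
  bit-reproducible for a fixed seed.
* Grid indexing uses half-open membership with 1e-9 slack so bin edges
  at node ages are deterministic.

## Limitations

* Constant-rate regimes cannot express within-regime rate decay or
  diffuse, tree-synchronous temporal trends (see the episodic-coupling
  discussion above); whole-tree rate-through-time curves from this
  model understate smooth temporal variation.
* On pure-birth data the posterior number of shifts is prior-dominated
  (the marginal Bayes factor of an extra shift is close to 1, and
  chance rate variation in a 100-tip tree can push it above 1), so the
  posterior mode of the shift count on null data sits at 0 or 1
  depending on the realization — the familiar overfitting tendency of
  compound-Poisson shift models.
* The heuristic search has no TBR/ratchet moves; on conflict-rich
  matrices it can miss the optimum (bounded here by the exhaustive
  oracle at small size).
* The t-test over posterior coefficients inherits the posterior's
  autocorrelation; its p-values are anti-conservative and flagged as
  such in the output.
* The multi-tree MAST is an iterated pairwise heuristic and depends on
  input order.
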