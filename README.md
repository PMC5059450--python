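# paleodiv

Tools for asking a macroevolutionary question end to end: **does
speciation rate track global palaeo-temperature?** The package
implements the full inference chain used to answer it for clades known
only from overlapping published phylogenies — such as marine
invertebrate groups whose richest data are source trees rather than
molecular supermatrices:

1. **Supertree assembly** — source trees are combined by matrix
   representation with parsimony (MRP): every informative clade becomes
   a binary character (1 = subtended, 0 = not, `?` = taxon absent),
   rooted with an all-zero hypothetical outgroup; most-parsimonious
   supertrees are found by random-addition + NNI search (with an
   exhaustive-enumeration oracle at small size), summarized by
   strict/majority consensus, and conflict can be pruned with rooted
   maximum agreement subtrees.
2. **Fossil time-scaling** — fossil first occurrences give minimum ages
   at crown or stem nodes; the 'equal' rule dates the remaining nodes
   by dividing the free interval equally along uncalibrated chains,
   with a 0.1 Myr minimum branch length; calibration sets can be
   perturbed (moved to parent/child nodes) for robustness reruns.
3. **Diversification** — a compound-Poisson birth–death shift model: a
   root regime (λ, μ) plus shifts starting new constant-rate regimes on
   branches, with per-tip sampling fractions f in the reconstructed-
   process likelihood (E′ = μ − (λ+μ)E + λE², D′ = −(λ+μ)D + 2λED),
   sampled by reversible-jump MCMC (optionally Metropolis-coupled).
   Output: per-branch marginal shift probabilities with Bayes factors,
   and speciation-rate-through-time curves on a 0.1 Myr grid.
4. **Climate correlation** — a δ¹⁸O series is smoothed (running mean),
   negated into a warmth-increasing temperature proxy, interpolated
   onto the rate grid, and correlated with *every* posterior rate curve
   using Pearson's r and the detrended cross-correlation coefficient
   ρ_DCCA(s); the coefficient distribution is summarized by a t-test of
   its mean against zero. A mean of −1 reads "speciation faster when
   cooler", +1 "faster when warmer".

A `synthgen` module generates every input with known ground truth
(birth–death trees with planted shifts, AR(1) isotope-like records with
optional cooling trends, temperature-coupled histories, source-tree
decompositions, fossil-like calibrations), so the whole chain is
testable without any downloads.

## Worked example (CLI)

Build everything from synthetic data — a model tree, overlapping source
trees, an MRP matrix, a search, a posterior and a climate correlation:

```sh
paleodiv synthgen tree --lam 0.1 --ntips 12 --seed 4 > model.nwk
paleodiv synthgen sources model.nwk --k 4 --tips-per-tree 6 --seed 1 > sources.nwk
paleodiv supertree encode sources.nwk | head -4
```
```
#NEXUS
BEGIN DATA;
  DIMENSIONS NTAX=13 NCHAR=16;
  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;
```

13 rows (12 taxa + `MRP_Outgroup`) and 16 clade characters. Search and
date a tree, run the shift sampler, and correlate against a synthetic
isotope record:

```sh
paleodiv supertree search sources.nwk --replicates 4 --seed 2 --out best.nwk
# best length: 16 (105 trees)   <- compatible characters, many ties on 4 small sources
paleodiv synthgen tree --lam 0.12 --ntips 25 --seed 9 > dated.nwk
paleodiv synthgen proxy --phi 0.9 --sd 0.1 --span 0 60 --trend 0.02 --seed 3 --out iso.csv
paleodiv shiftbd run dated.nwk --generations 2000 --store 200 --seed 3 --out events.csv
paleodiv shiftbd rtt dated.nwk events.csv --out rtt.csv
paleodiv correlate rtt.csv iso.csv --method pearson
```
```json
{
  "method": "pearson",
  "mean": 0.1360852531935904,
  "se": 0.034777417076885773,
  "t": 3.9130350851742004,
  "p": 0.0001646264828850669,
  "n": 103,
  "n_degenerate": 77,
  "note": "posterior draws are autocorrelated; the t-test treats them as independent, so the effective sample size is overstated"
}
```

Here 103 posterior rate curves had a defined correlation with the
temperature proxy (77 zero-shift draws give exactly constant curves, so
no coefficient exists for them); their mean of +0.14 would read
"speciation faster when warmer" — unsurprisingly weak, since this toy
tree was simulated with *no* climate coupling, and on such small
synthetic runs the t-test's significance should not be taken at face
value (see the note field, and docs/methods.md).

The same chain is available as one command over a YAML config, rerun
per calibration-perturbation fraction (0/10/15/20% of dates moved):

```sh
paleodiv pipeline config.yaml   # writes report.json + pipeline.log
```

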