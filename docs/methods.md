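# Methods

## Problem setting

A fractionated AP-MS screen purifies each tagged bait protein twice — once
from the chromatin-bound fraction of the lysate, once from the soluble
fraction — and identifies co-purifying preys by MS/MS spectral counting. The
analytical task is to separate genuine bait–prey interactions from the two
dominant noise sources (matrix-binding background and abundant cellular
proteins that co-purify with any overexpressed bait), *per fraction*, and
then to compare the on- and off-chromatin interactomes.

## Statistical model

Counts are treated as independent Poisson draws. The design is *two-pool*: a
dedicated negative-control pool (vector-only purifications plus unrelated
baits processed identically) estimates the false-interaction distribution,
and the bait (sample) pool is scored against it.

**Background.** For prey *i*, the false rate is the pseudo-counted
control-pool average `lambda_F,i = (sum_j X_ij + eps) / sum_j exp(c_j)` over
control purifications *j*, with `eps = 0.1` so rates are strictly positive.
Depth offsets `c_j = log(TSC_j / median TSC)` are available
(`normalize_by_total`) but off by default — purification depths in this kind
of screen are of comparable order and raw counts keep the Poisson model
exact. With `fraction_stratified` (default on) the chromatin and soluble
backgrounds are estimated from fraction-matched controls; a purification of
the "combined" fraction belongs to both control pools, and a fraction with
no matched control falls back to the pooled background.

**Interaction probability.** For each bait, fraction and prey with a
non-zero count in at least one replicate, the true-component rate
`lambda_T` is fitted by EM on the bait's replicate counts under the
two-component mixture with fixed prior `pi = 0.1`. `lambda_T` is initialized
at the depth-scaled replicate mean and floored at `2 * lambda_F,i` so the
true component always dominates; EM is deterministic (no random starts) and
typically converges in a handful of iterations (tolerance `1e-8`, cap 200
iterations; non-convergence is flagged, never fatal). The replicate
posterior is the closed-form two-Poisson Bayes ratio; replicates are
combined by mean (configurable to max). If `lambda_T` ever collapses onto
`lambda_F` the posterior is set to the prior and flagged as uninformative.

**Contaminant score.** `mu_i = log(lambda_F,i) - log(baseline)`, where the
baseline is a quantile of the control abundance spectrum over preys observed
in at least one control. The baseline quantile is 0.90 by default: a prey in
the top decile of control abundance is, operationally, a common contaminant
or an abundant non-specific binder. A central (median) baseline is available
via `mu_baseline_quantile=0.5` but would flag half of all observed preys —
inconsistent with the score's purpose of marking the abundant *tail*. The
score is computed from the pooled control set (not per fraction): a
contaminant is a property of the purification chemistry, not of the
fraction.

**Dual filtration.** HCIPs are interactions with probability strictly
greater than 0.80 AND `mu_i < 0`, the mu filter acting at prey level (a
flagged prey is removed from every bait and fraction). No outlier removal is
performed anywhere.

**Bait self-handling.** The bait's own prey row is zeroed in all of its own
purifications before background estimation and scoring — the overexpressed
bait otherwise inflates its own abundance estimates. Masking covers
unrelated-bait *control* purifications too (they are real TAP experiments
with self counts); only sample-pool self cells are re-added to the HCIP
table, flagged `is_bait_self`, restricted to the fractions where the bait
was actually detected, and exempt from both filters. The self ledger makes
the masking exactly count-conserving.

## Prey atlas

Per prey (restricted to preys seen in the TF group): `abundance` = log mean
depth-normalized rate over all purifications; `tf_specificity` = log rate
over the entire group minus log rate over the control group;
`fraction_specificity` = log rate over chromatin purifications minus log
rate over soluble purifications (all rates pseudo-counted with `eps`).
Colour categories partition the (fraction_specificity, tf_specificity)
plane: grey below the `green_band` (0.3), green up to `specificity_min`
(1.0), and above that red / blue / purple for chromatin-enriched /
soluble-enriched / no preference at `fraction_margin` (1.0 log unit). The
boundaries are visual conventions, hence plain configuration; the defaults
put clear contaminant tails in grey and strong fraction preferences
(≈ e-fold ratio of 2.7×) in red/blue.

## Downstream analyses

*Fraction overlap* counts bait–prey pairs HCIP under both fraction labels;
because the natural denominator is ambiguous (distinct pairs, table rows, or
the smaller fraction), all three percentages are reported, with distinct
pairs as the headline. *Per-bait TSC* sums counts over a bait's own
purifications restricted to its non-self HCIP preys, per fraction.
*Replicate reproducibility* at threshold *t* is the fraction of one
replicate's HCIPs with reference count ≥ *t* that recur in the other
replicate, averaged over both directions; the estimator conditions on the
reference replicate's count (not the max), which keeps the two directions
symmetric in construction. *Reciprocal validation* marks a forward pair
recovered when the prey's own purification returns the bait as an HCIP in
any fraction, and fraction-matched when the detection fraction sets
intersect. *Reference overlap* intersects non-self HCIP pairs with an
undirected reference edge list supplied by the caller (no interaction
database is bundled).

## Synthetic data

The generator emulates the screen's statistical structure with, as defaults,
the study-shaped conditions: 56 baits × 2 fractions with 4 extra replicated
baits per fraction (60 + 60 sample purifications), 61 unrelated-bait
controls alternating fractions plus 9 vector-only controls (4 chromatin, 4
soluble, 1 combined) — 190 purifications — and 3,700 preys. Per-prey
background rates are `lambda_false = 0.035` scaled by a log-normal factor
(σ = 0.5) so the control-abundance spectrum is non-degenerate; 5% of preys
are contaminants with a 20× background boost; each bait gets a
Poisson-distributed number of true edges per fraction (mean 18, 5% shared
between fractions) drawn from non-contaminant preys, each adding
`lambda_true = 25` to the cell rate; every tagged protein (baits and
unrelated-control baits alike) receives self counts with mean 30. These
rates put per-purification identifications and totals in the realistic
range for a deep TAP/MS screen (the default run yields ≈ 46 k non-zero
identifications over 190 purifications, ≈ 245 per run).

What the generator does *not* model: peptide-level identification and
protein inference, length-dependent detectability (prey lengths are drawn
but not used in the rates), correlated contaminant structure across
purifications of the same batch, PTMs, and shared complexes between baits
(edges are independent per bait). Passing recovery tests on these
simulations therefore demonstrates the estimator recovers the generating
model at realistic depth and design — not that real chromatin/soluble
purifications satisfy the independence assumptions.

True edges are planted on non-contaminant preys: the contaminant filter is
only meaningful when true partners are not themselves ubiquitous background
binders, and planting edges on contaminants would measure the overlap of
the two planted sets rather than the method.

## Numerical choices and degenerate inputs

Posteriors are evaluated in log space and are exact to well below 1e-9
against a direct Bayes evaluation. Missing counts are zeros by definition
(spectral counting has no NA). Zero-count preys for a bait are not emitted.
An empty control pool, an all-zero control pool, unknown fraction/pool
tokens, duplicate ids and negative or fractional counts are hard errors
with the offender named. Table round trips are bit-exact for integer
columns and to 12 significant digits for scores. Scoring, filtration and
the pipeline are fully deterministic given inputs; the only randomness in
the package is the simulation seed.

## Problem sizes

The test suite and the acceptance script use the study-shaped scale
(3,700 preys, 190–294 purifications), which runs the full chain in a few
seconds, plus small hand-checkable toys for every formula. The recovery
analysis uses 2 replicates per bait and fraction — the single-replicate
posterior from one spectral count is intrinsically weakly identified, and
the replicated design is where the mixture's sensitivity/specificity
trade-off is meaningfully measured.

## Known limitations

* The mixture is an empirical-Bayes point-estimate variant: `pi` is fixed,
  `lambda_T` is a per-triple MLE, and no uncertainty is propagated into the
  posterior. A fully Bayesian treatment would shrink low-count triples
  harder.
* With a single replicate, a count of 2–3 on a prey with near-zero control
  background already clears 0.80; replication is the real guard against
  such singletons.
* The contaminant baseline quantile (0.90) is a design constant of the
  score's semantics, not estimated from data; screens with very different
  contaminant loads may warrant adjusting it.
* Identifier namespaces (bait ids vs prey ids) must already be reconciled
  by the caller; no gene-symbol mapping is attempted.
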