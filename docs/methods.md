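# Methods

This note records the models, parameter choices and numerical
conventions behind `ednafi`, and what the synthetic validation does and
does not establish.

## Reference-condition models

Each index metric is regressed on eight environmental descriptors at
least-disturbed reference sites: upstream catchment area, river slope,
river width, mean annual air temperature at the site and over the
catchment, annual rainfall, hydrological regime and dominant sediment.
Species-count metrics use a Poisson GLM with log link; proportion
metrics a binomial GLM with logit link, with the number of
trait-resolved taxa as the variance weight (quasi-binomial when no
denominator is available).  Area, width and slope are log-transformed;
all continuous predictors are affinely rescaled with *fixed* constants
(not data moments) so that a serialized model set is independent of the
sample it was fitted on; categorical descriptors are dummy-coded
against declared levels.  Fitting requires at least ten reference sites
per encoded predictor; singular designs are rejected with the offending
columns named.

The residual spread σ_m of metric *m* is the sample standard deviation
(n−1) of link-scale residuals across reference sites, with
g(y) = log(y + ½) for counts and a logit clipped at 10⁻³ for
proportions.  A metric with σ_m below 10⁻⁶ is flagged degenerate and
floored rather than dropped.

## EQR, aggregation, classification

The EQR of an observed metric is Φ(z) (orientation "decreases") or
1 − Φ(z) (orientation "increases"), with z the standardised link-scale
residual against the model's expectation; EQRs are clipped to
[0.001, 0.999].  A site indistinguishable from reference scores ≈ 0.5
on every metric by construction.  The published normalisation of the
original French index is not public, so this probability-transform form
is a documented stand-in with the same qualitative behaviour (bounded,
symmetric, orientation-aware), not a re-implementation of the published
coefficients.

The index is the mean of the k lowest EQRs; k defaults to the lowest
half (5 of 10, 3 of 6).  Ties at the cut are resolved by sorting on
(EQR, metric name), which makes aggregation deterministic.

Classification uses four strictly decreasing boundaries with a closed
lower bound (a score exactly on the Good/Moderate boundary is Good).
Boundaries are river-type specific in operational use; the package
default (0.8, 0.6, 0.4, 0.2) is an even partition supplied for
user-driven assessments.  For the synthetic study the boundaries are
instead *calibrated*: the Good/Moderate boundary is placed at the 1 %
quantile of index scores of an independent batch of undisturbed sites
(guarded ≥ 0.005, strictly above the index floor, so that degraded
states remain expressible), the High/Good boundary at the 25 %
quantile, and the remaining boundaries split the interval below Good
evenly.  Calibration is out-of-sample because in-sample reference
scores are optimistic (their residuals are shrunk by the fit).

## Guild metrics

Presence for eDNA data means at least one read after discards; no
minimum-read threshold is applied by default, though one can be passed.
Denominators of relative-species metrics count only present taxa with
resolved trait profiles; excluded taxa are logged, never silently
dropped from the denominator.  Species-accumulation curves enumerate
all campaign orderings exactly whenever their number does not exceed
the requested permutation count (default 999), and fall back to seeded
random permutations otherwise.

## MOTU processing conventions

Discard policies are explicit taxon → reason maps (farmed-only,
stocking, lentic-transport, other); percent rows are re-closed to 100
after removal and flagged as renormalized.  A multi-species MOTU
inherits a profile shared by all members, else the profile of a member
holding ≥ 95 % of the reference catch for that MOTU, else it is
excluded from guild metrics (but not from whole-assemblage richness).
Replicate pooling sums reads *before* proportions are computed,
preserving count semantics for model offsets.  Count-to-percent
conversion closes each row to exactly 100 at the output precision by
largest-remainder rounding.

## Comparison statistics

Method effects on richness metrics are tested with a Poisson GLM
(method + stretch); metrics based on numbers of individuals use a
negative-binomial GLM with a log-total-individuals offset, dispersion
estimated by maximum likelihood, falling back to quasi-Poisson with a
logged warning when the NB fit does not converge.  The 2×2 association
test applies the Yates continuity correction with the correction term
clamped at zero.  Percentage shares are reported round-half-up to one
decimal and always recomputed from counts.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not any particular river basin:

* **Species pool.** The 33 MOTUs of the packaged survey table with
  their comparison-guild profiles.  Index guilds are synthetic
  assignments: omnivorous and tolerant reused; limnophilic =
  phytophilic; stenothermal a curated cold-water list; the sensitive
  guilds (oxyphilous, intolerant, habitat-degradation intolerant,
  running-water spawning) curated so that no two abundance guilds share
  more than half their members — the same dissimilarity rule multimetric
  indices apply to their metrics, and necessary for the metrics to
  carry complementary information.  Baseline weights are the table's
  mean eDNA shares with a small floor.
* **Environments.** Catchment area log-uniform over 28–74 447 km²;
  width and slope follow area (wider, flatter downstream) with
  lognormal scatter within 4–163 m and 0.07–44 ‰; temperate
  temperature and rainfall ranges; three-level regime and sediment
  factors.
* **Communities.** Taxon log-weights shift along the
  upstream–downstream axis (tolerant/eurytopic/omnivorous up,
  rheophilic and cold-water taxa down; cold-water taxa also track air
  temperature), with lognormal site scatter (sd 0.3).  Occupancy is
  thinned with presence probability 1 − exp(−share/0.002), so rare taxa
  are genuinely absent from some sites.
* **Disturbance dial d ∈ [0, 1].** Log-abundances shift by ±2·d
  (sensitive taxa down, tolerant/eurytopic/omnivorous up; sensitivity
  takes precedence for taxa in both camps — the pool's cold-water taxa
  are classed eurytopic, and without precedence their response would
  cancel).  Sensitive taxa whose shifted share falls below 0.008·d are
  extirpated; without local extinction, species-ratio metrics would be
  blind to disturbance.  d = 0 is exactly the identity.
* **Electrofishing.** Multinomial catches with weights = true shares ×
  bias factor (pelagic ×5, benthic ×0.3 by default — magnitudes are
  calibration choices reproducing the qualitative cross-method
  contrast, as only directions are documented), catch size Poisson
  around the effort (300 individuals/campaign).
* **eDNA.** Per capsule, reads are Dirichlet-multinomial around truth ×
  shedding factors at depth 500 000.  The Dirichlet precision
  (10 000) is anchored on the reported reproducibility of replicate
  capsules: with ten capsules it yields pair-combination CVs of the
  index of order 0.01–0.1.  Standard effort is two capsules pooled.
  With all bias factors at 1 and precision → ∞ the two methods are
  statistically equivalent (the negative control used in tests).

## The synthetic validation: what it shows

With the defaults above, the package's validation study (reference
network of 300 sites, boundary calibration on 300 further undisturbed
sites) establishes, across independent seeds:

* reference-model coefficients are recovered within 2 standard errors
  for ≥ 90 % of parameters on 500 generator-drawn sites;
* ≥ 95 % of fresh undisturbed sites classify good and ≥ 95 % of fully
  disturbed sites classify degraded;
* in a paired dose-response design — each site evaluated along its own
  disturbance trajectory with common random numbers, the standard
  variance-reduction design for isolating a treatment effect in
  simulation — the six-metric index decreases monotonically in d
  (pooled Spearman ρ ≈ −0.85);
* simulated electrofishing inflates pelagic and deflates benthic
  relative-abundance metrics relative to truth, and single-campaign
  electrofishing richness is below eDNA richness, converging as
  campaigns accumulate.

These are properties of the generator-plus-pipeline system.  They show
the implementation is internally coherent and directionally faithful;
they do not validate the index against real river data, which would
require the unpublished national model coefficients and raw samples.
Real eDNA data also carry features the generator omits: contamination
and false positives, upstream DNA transport, PCR primer bias beyond a
static per-species shedding factor, and temporal autocorrelation of
shedding with season and spawning.

## Known limitations

* The EQR normalisation and the aggregation depth k reproduce the
  *form* of the published index, not its coefficients; absolute scores
  are not comparable with published values.
* Cross-metric residual correlation (≈ 0.3 among composition metrics,
  an unavoidable consequence of compositional closure) widens the
  index's reference distribution and caps the sharpness of cross-site
  dose-response correlations near −0.8.
* The dominance rule for MOTU trait assignment uses whatever reference
  catch table is supplied; with the packaged fixture this is per-cent
  abundances pooled over stretches, a proxy for the raw individual
  counts, which are not public.
* Boundary calibration assumes the reference network is genuinely
  least-disturbed; contamination of the reference set with degraded
  sites lowers the Good boundary and inflates apparent status.
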