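# Methods

## The problem in one paragraph

Migratory frugivores can deposit large numbers of viable seeds in
places where the plant cannot establish. We call a dung pile a *wasted
dispersal event* for species *s* when it contains at least one seed of
*s* and the modelled habitat suitability at its location lies strictly
below the species' *survival limit* — the minimum suitability at which
living plants of *s* were recorded in vegetation plots. Because the
limit is a property of the species' response, not of any particular
map, the same value is reused when re-evaluating the classifier on
future-climate suitability surfaces; what changes across scenarios is
the suitability at the (fixed) pile locations.

## Maximum-entropy suitability model

**Estimator.** Among distributions *q* over the background sample, the
model maximises entropy subject to per-feature constraints
|E_q[f_j] − mean of f_j over presences| ≤ β_j. The dual is the
L1-regularised convex program

    f(λ) = −mean_presence[λ·f(x)] + log Σ_background exp(λ·f(x)) + Σ_j β_j |λ_j|.

We solve it exactly with a split-variable formulation (λ = u − v,
u, v ≥ 0) and bound-constrained L-BFGS, then verify the KKT conditions
of the original problem: each feature's constraint violation must not
exceed β_j (tolerance 1e−5 scale, iteration cap 5000). Up to three
polish restarts clear the quasi-Newton memory if the first pass stops
on a flat step. Unit tests check the solution against an independent
iterative-zoom exhaustive grid search of the same objective on tiny
instances (agreement ~1e−7, contract 1e−3).

**Features.** Linear and quadratic transforms of each covariate, scaled
to [0, 1] by their min/max over the training background and clamped
outside that range — the clamp doubles as the extrapolation guard when
projecting onto scenario climates. Product features are available but
off by default; hinge/threshold/categorical features are out of scope.
Constant covariates are dropped with a warning.

**Regularization.** β_j = multiplier × sqrt(s²_j / m) with s²_j the
feature's background variance and m the presence count (multiplier
default 1.0) — the usual confidence-width rationale: slack shrinks as
root-m.

**Outputs.** Raw: q(x) = exp(λ·f(x) − log Z), normalised over the
training background (Σ raw = 1 to 1e−9, asserted in tests). Logistic:
L(x) = e^H q(x) / (1 + e^H q(x)) with H the entropy of the fitted
background distribution — the τ = 0.5 convention, under which a
no-signal model scores 0.5 everywhere. Logistic is a monotone transform
of raw, so cell rankings and AUC are identical under either.

**Evaluation.** AUC is rank-based (Mann–Whitney with ties counted 0.5)
between presence and background scores, with the conventional verbal
grades (>0.9 very good, >0.8 good, >0.7 useable). Bootstrap ensembles
resample presences with replacement, hold out 30% of the resample for
testing, fit on the rest, and average the logistic surfaces cell-wise
(default 100 replicates); the report carries per-replicate AUCs, their
mean, and the mean cell-wise SD across replicates — both plausible
readings of a "replicate SD", deliberately labelled as such. Replicates
whose fit fails are skipped; more than 20% failures aborts.

**Predictor selection.** One single-predictor model per candidate;
gain = regularised mean presence log-likelihood improvement over the
uniform background model (≥ 0 by construction). The k highest gains are
kept; ties (including degenerate constant predictors at gain 0) are
broken by input order via a stable sort.

## Range change

Current and future surfaces are binarized at `suitability ≥ threshold`
(closed at the threshold — the complement of the strict `<` rule for
wasted dispersal, so a cell exactly at the limit is habitable and
not wasted). The four transition classes (lost, gained, stable-suitable,
stable-unsuitable) partition the land cells exactly; percentages are
reported against both denominators in field use — all land cells and
currently suitable cells — because published range-shift figures switch
between them without notice. The default threshold is the species'
survival limit, overridable.

## Occupancy GLM and goodness of fit

Presence in plots is modelled as Bernoulli with
logit(p) = β₀ + β₁ × suitability, the single covariate being the mean
ensemble logistic suitability at the plot cell. The fit is IRLS to a
deviance change below 1e−8, with Wald standard errors from the final
weighted information matrix; agreement with direct numerical likelihood
maximisation and with statsmodels is asserted in tests to 1e−6.
Perfect separation — which a hard occupancy threshold can genuinely
produce — is detected (diverging slope, fitted probabilities pinned to
0/1) and surfaced as an error; the pipeline records it as a diagnostic
rather than aborting.

The Hosmer–Lemeshow statistic sorts observations by fitted probability,
cuts at the fitted-value quantiles into g groups (default 10; ties stay
in one group, reducing g — the classic formulation's known
implementation-sensitive point), and sums
(O_g − n_g·p̄_g)² / (n_g·p̄_g·(1 − p̄_g)) with df = g − 2. Calibration is
verified by simulation: refitting on data generated from a fitted
model, the statistic's mean over 200 replicates at n = 10,000 falls
within 8 ± 0.5, as a χ²₈ variable should. Published HL values from the
original field data depend on an unknown grouping dialect and fitted
surface and are not reproduction targets.

## Flux and front arithmetic

Seed flux: Δseeds/day = N × defecation rate × mean seeds per pile ×
(wasted_now − wasted_future), with the *all-pile* mean (zeros included)
since every defecation event contributes; years are 365 days. Front:
m/yr = advance distance / horizon; m/generation = m/yr × generation
time. The default 55-year horizon reads a mid-2010s baseline against a
2070 scenario — an inference, flagged as such, but the only horizon
consistent with both a 27 m/yr rate and a 218 m/generation requirement
for 1,500 m of advance and 8-year generations.

## Synthetic island

**Geometry.** A radial cone (peak 860 m, the height of the emulated
island) plus smoothed low-frequency relief, clipped to [0, peak]; sea
is everything beyond the coast radius. Grid convention: projected
metres, cell-centre registration, row 0 at the north edge; default cell
100 m.

**Climate.** Temperature layers decrease with elevation at the standard
environmental lapse rate of 6.5 °C/km; precipitation layers increase
with elevation (arid lowlands, humid highlands) and share a smooth
windward/leeward "moisture anomaly" field that is independent of
elevation. The anomaly is essential: without it every climate layer is
a deterministic function of elevation, predictor selection among them
is a coin flip, and a scenario's effect on the fitted model would be
arbitrary. Two smoothed pure-noise layers act as decoys for predictor
selection. Scenarios shift temperature layers additively everywhere and
add an elevation-tapered increment to precipitation layers (full value
at the coast, zero at the summit). The demo scenarios use +1.4 °C /
+40 mm (2050) and +1.8 °C / +70 mm (2070); the temperature deltas are
the published RCP4.5 mid-century and late-century global figures.

**True suitability.** The product of two optional factors: a Gaussian
elevation response exp(−0.5((z−z₀)/b)²) and a logistic response
σ(intercept + Σ c_k x̃_k) in land-standardised covariates, scaled by a
maximum suitability. Either factor can be disabled; with only the
elevation factor the optimum attains the maximum exactly and the
response is symmetric, with only the logistic factor and zero
coefficients the surface is constant. The demo species are
σ(−1 + 2.2·precip_drỹ + 1.2·precip_wet̃) (guava-like:
precipitation-limited, excluded from arid lowlands) and
σ(−0.8 − 2.0·temp_max̃) (passionfruit-like: cool-adapted).

**Survey data.** Occurrences are accept–reject samples proportional to
true suitability at cell centres (1,621 / 1,435 records by default,
then cleaned of sea cells and elevation outliers). Plots sit on two
slope transects (LR south, CF east) at the 50 m elevation levels of the
emulated design — 9 levels × 4 plots = 36 at LR (10–400 m), 7 × 4 = 28
at CF (100–400 m) — with presence Bernoulli under a
threshold-plus-logistic occupancy rule: zero below the generating
survival threshold, σ(a + b·s) above it. Dung-pile locations are
stratified round-robin across 50 m elevation bands (mirroring a
collect-on-crossing survey design and guaranteeing below-limit cells
are represented; area-uniform sampling is available); seed loads are
zero-inflated shifted negative binomial — presence probability ×
(1 + NB) — calibrated to the emulated survey's positive-pile means
(1,443 and 246 seeds) and heavy overdispersion (SD > mean; dispersion
0.5 and 0.25). Loads are independent of location: the disperser carries
seeds wherever it roams, which is exactly what makes lowland deposition
wasted. Default pile counts are 159 (LR) + 63 (CF) = 222.

**What the generator does not emulate.** Real geography and real
climate fields; spatial autocorrelation of occupancy beyond the
suitability surface itself; seed loads that covary with elevation
(in the real survey wasted piles carried disproportionately few seeds —
seed-weighted wasted fractions here are therefore closer to pile-weighted
ones than in the field data); spatially heterogeneous climate scenarios.
The last point matters for interpretation: a spatially *uniform* +1.4 °C
shifts the thermal niche ~215 m upslope on a 6.5 °C/km lapse, so the
cool-adapted demo species' wasted fraction saturates at 100% of its
piles under the 2050 warming scenario, where heterogeneous scenarios in
the field study produced 58–75%. Passing tests demonstrate the
machinery and its qualitative behaviour (pile minima strictly below
plot minima; wasted fraction falling under lowland wetting, rising
under warming), not quantitative transfer to any real landscape.

## Numerical and design choices

* "Below the survival limit" is strict (<); ties are presence-compatible
  and not wasted. "Suitable" in range change is ≥. The two rules are
  complements, so the conservation identities hold exactly.
* Percentages are computed at full precision; presentation rounds
  half-away-from-zero to 1 decimal (2 where field tables print 2).
  Wasted-pile percentages are reported against both the
  species-containing-pile and the all-pile denominator, labelled,
  because field reports use both.
* Positive-pile seed-load SD is the sample SD (ddof = 1).
* Background sampling is uniform over land cells, without replacement
  when n does not exceed the number of land cells (with replacement
  otherwise); presences are not added to the background.
* Raster I/O uses ESRI ASCII grids with a JSON sidecar (one fixed,
  documented convention); values round-trip to 1e−6, masks and
  georeferencing exactly. Tables are UTF-8 comma CSV with headers and
  '.' decimals; validation errors carry 1-based row numbers.
* All samplers are pure functions of their seed; pipeline bundles carry
  the seed and a SHA-256 of the config, contain no timestamps, and
  re-run byte-identically.
* Demo problem sizes (90×90 island, 400/350 occurrences, 3,000
  background points, 8 bootstrap replicates) are the package's quick-run
  choice; the full-size configuration (160×160, 1,621/1,435 occurrences,
  10,000 background, 100 replicates) runs in well under a minute on one
  core.

## Known limitations

* The maxent implementation targets the estimator's contract (objective,
  KKT, outputs), not bit-compatibility with any legacy implementation;
  hinge features and MESS-style novelty maps are absent.
* Jackknife gains of strongly collinear predictors are nearly equal, so
  selection among them is effectively arbitrary — a property of the
  statistic, visible on the synthetic island whenever the moisture
  anomaly is small.
* The occupancy GLM uses a single covariate by design; no spatial
  autocorrelation correction is attempted.
* The flux/front projections are deliberate back-of-envelope arithmetic,
  linear in every input; they inherit every uncertainty of the wasted
  fractions and front distances fed into them.
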