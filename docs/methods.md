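# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices and the known limitations of the `inactivity`
package.

## Problem and observation model

The quantity of interest is the prevalence of insufficient physical
activity — adults failing to reach 150 min/week of moderate-intensity
activity, 75 min/week of vigorous activity, or an equivalent combination —
by country, year (2000–2022), sex and seven age bands (18–29, 30–39, …,
70–79, 80+). Data arrive as survey-level prevalences `p̂` with effective
sample sizes, heterogeneous in instrument, coverage and design.

Each observation is transformed to the probit scale,
`y = Φ⁻¹(p̂)`, with delta-method sampling variance

```
v = p̂(1 − p̂) / (n_eff · φ(Φ⁻¹(p̂))²).
```

Boundary prevalences are continuity-corrected first (`0 → 1/(2n)`,
`1 → 1 − 1/(2n)`); how boundary observations should be handled is not
settled practice, and the correction is configurable in spirit — it only
matters for tiny strata. A summary-level normal likelihood with this
variance is the standard construction for pooled prevalence surfaces when
the individual data behind each survey are unavailable; an individual-level
binomial-probit likelihood would be the natural alternative and is noted as
an extension.

## Mean structure

```
μ = β₀ + u_region + u_country
  + (γ₀ + g_region + g_country)(year − 2011)
  + s(age)ᵀ(θ + θ_region)
  + δ_instrument
  + λ·covariate(country, year)
```

* **Hierarchy.** Region and country intercept deviations `u` and slope
  deviations `g` are zero-mean normal with unknown SDs. This shares
  information across countries — strongly where data are sparse, weakly
  where data are rich.
* **Time.** Trends are linear on the probit scale. The reference year is
  2011, the window midpoint, to decorrelate intercepts and slopes (the
  choice affects only parameter interpretation).
* **Age.** A natural cubic spline with interior knots at ages 30 and 60
  and boundary knots at 18 and 85 (linear beyond the boundaries; ages
  outside are clamped). The basis is the truncated-power natural basis on
  an age axis normalised to [0, 1], giving three O(1) columns; coefficients
  have a global level plus region deviations. Band prevalences enter at
  the band midpoint; the open-ended 80+ band is closed at 97, so its
  midpoint is 88.5.
* **Instruments.** Fixed reporting offsets for IPAQ-short, Eurobarometer
  and "other", with GPAQ as the zero reference, all sexes and regions
  sharing one offset per instrument.
* **Covariate.** A country-year obesity-prevalence analogue, centred at
  its grand mean, with a single coefficient.
* **Extra variance.** `τ²` adds to every observation's sampling variance,
  with separate values for national and subnational surveys (subnational
  data are noisier for reasons beyond sample size).

Sexes are modelled independently throughout.

### Priors

Normal(0, 1) on all fixed coefficients (probit scale) and half-normal(0,
0.5) on every SD and τ. These are weakly informative at the scale of
probit prevalences; the per-year slope SDs are O(0.01), so the same
half-normal is effectively flat for them. All scales are configurable per
parameter (`ModelConfig.prior_sd_scale_overrides`).

## Inference

Conditional on the seven scale parameters the model is exactly
linear-Gaussian. The sampler exploits this:

1. each scale is updated by univariate slice sampling (stepping-out and
   shrinkage, on the log scale) against the *marginal* likelihood with all
   coefficients integrated out, evaluated via the Woodbury identity
   (`O(n·p² + p³)` per evaluation);
2. the full coefficient vector is then drawn from its exact
   multivariate-normal conditional.

Because the scales are sampled from their collapsed posterior, there is no
centred/non-centred funnel and mixing is near-independent. Four chains
with over-dispersed scale initialisations are run by default; 4000 joint
draws are retained (`n_draws`), and split-R̂ < 1.05 plus a per-parameter
ESS floor (default 100) are enforced via ArviZ — a fit failing the gate
raises with its diagnostics rather than returning silently. Test and
acceptance fits use reduced draw counts with proportionally reduced ESS
floors; problem sizes are stated in each test.

### Prediction

Posterior surfaces evaluate μ on the full country × year × age grid with
the instrument at the GPAQ reference and the observed covariate;
prevalence is `Φ(μ)`. τ² is a measurement-level term and is **not** added
to predictions. Countries with no data receive, per draw, their region's
level plus fresh country-level deviations drawn from that draw's hierarchy
SDs — the model's shrinkage prediction — deterministically seeded.

## Aggregation

All aggregation is draw-wise. Crude prevalence population-weights the
grid cells. Age-standardisation uses fixed weights (the WHO world
standard collapsed to the seven adult bands is the shipped default,
overridable): each country is standardised first, then countries are
combined weighting by 18+ population — matching how country-level
age-standardised values are reported alongside regional ones; 18+ rather
than total population is used because the outcome is defined on adults.
Both-sex surfaces are cell-wise population-weighted means with draws
paired by index; since sexes are fitted independently, this pairing treats
cross-sex dependence as absent — a documented caveat. Point estimates are
posterior means (configurable in principle to medians); intervals are
2.5th/97.5th percentiles with linear interpolation.

## Target tracking

The target is a 15% relative reduction between 2010 and 2030. Per draw
and unit, `probit(p₂₀₃₀) = probit(p₂₀₂₂) + 8 · (country total slope)`,
the covariate frozen at its last value; aggregation then uses target-year
populations. Extrapolating unit-level draws (rather than the aggregated
series) is deliberate: changing population structure makes the aggregate
trajectory nonlinear even under linear unit trends. Since trends are
linear over 2000–22, the fitted slope *is* the 2010–22 trend.

The posterior probability of meeting the target is the fraction of paired
draws with projected ≤ 0.85 × baseline (exact attainment counts as met).
Categories combine a central call — posterior-mean projection vs reduced
posterior-mean baseline — with that probability: on track with higher
(pp ≥ 0.80) or lower certainty, off track with higher (pp ≤ 0.20) or
lower certainty; the boundaries follow the printed ≥/≤ conventions.
Posterior probabilities of a true increase/decrease are the fractions of
paired draws moving each way (ties count toward neither).

## Synthetic worlds

The generator draws ground truth from the same structural family the model
assumes: hierarchical intercepts/slopes, region-varying spline age
patterns, a covariate effect, instrument offsets, an urban-coverage
offset, and per-observation design noise plus binomial sampling. Defaults
are fixed once to emulate the observed global picture: prevalence around
26% at the 2011 reference (intercept Φ⁻¹(0.264)), a +0.01 probit/year
global trend (matching a rise from roughly 23% to 31% over 2000–22),
hierarchy SDs (0.35 region / 0.25 country intercepts; 0.008 / 0.006
slopes) chosen so country prevalence spans roughly 3%–66%, a +0.15 probit
IPAQ-short offset, extra SDs 0.05 (national) / 0.10 (subnational), and a
+0.1 probit urban-only offset (a nonzero value exercises the crosswalk;
the magnitude is arbitrary and configurable).

Individual GPAQ-style records are generated from a mixture — a point mass
of fully inactive respondents plus log-normal weekly minutes placed on the
correct side of the 150-minute rule and split into domains, every nonzero
domain value ≥ 10 minutes so cleaning never flips sufficiency. The
contract is the insufficiency fraction, not the minute distribution.

What the generator does **not** emulate: real geography and country names,
nonlinear or interrupted time trends (e.g. pandemic-era step changes),
within-country subnational heterogeneity, correlated sexes, non-ignorable
survey gaps, or questionnaire biases that vary by region or time. Passing
recovery tests therefore demonstrates the estimation machinery is correct
and calibrated *under the model's assumptions*, not that those assumptions
hold for any particular real dataset.

## Survey processing choices

* Sufficiency rule: insufficient iff `moderate + 2·vigorous < 150`
  min/week, exact at the boundary.
* GPAQ cleaning defaults: reject if summed weekly activity exceeds a
  16 h/day equivalent; zero weekly domain values under 10 minutes. Both
  thresholds are configurable; published cleaning protocols live behind
  citations, so the defaults capture their intent rather than a verbatim
  rule.
* Weighted prevalence uses Kish effective sample sizes `(Σw)²/Σw²`;
  strata under 25 respondents merge upward (the remnant merges downward),
  else drop with a logged warning. Full linearised design variance is out
  of scope.
* Crosswalks (urban-only coverage → national; IPAQ-low → insufficient) are
  probit-affine, `probit(p_adj) = a + b·probit(p_obs)`, with coefficients
  supplied by configuration (identity by default — real analyses must
  supply estimated equations). The probit scale was chosen over the
  prevalence scale for coherence with the model; an affine map there is
  closed under inversion, which the tests exploit.
* Eligibility: fieldwork in/after 2000, n ≥ 200, nationally representative
  or covering ≥ 3 areas, all-domain instrument. Multi-year fieldwork uses
  the midpoint year rounded down.

## Numerical notes and limitations

* Deterministic given seeds everywhere: worlds and surveys from the world
  seed (per-survey streams derived from design fields), MCMC from the
  model seed per chain, data-free-country augmentation from an explicit
  seed.
* The observation CSV schema is versioned; readers reject unknown versions
  and report malformed rows by line number. Posterior draws persist as
  zstd parquet plus a JSON sidecar; manifests carry config hashes, seeds
  and input hashes for exact provenance.
* Memory: a surface is draws × countries × years × bands of float64; the
  default synthetic study (4000 × 18 × 23 × 7) is ~0.2 GB across
  sex-specific and combined surfaces. A 197-country grid at 4000 draws
  needs draw thinning or year slicing.
* The likelihood is summary-normal, not binomial: for very small strata at
  extreme prevalences the delta-method variance is approximate.
* Country classification uncertainty is understated wherever real-world
  dependence (shared instruments, correlated survey timing) violates the
  independence assumptions above; uncertainty intervals do not reflect all
  sources of uncertainty.
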