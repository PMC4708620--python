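# Methods

## The model

The unit of analysis is a published cost-effectiveness estimate: a pair
(ΔC, ΔE) of mean incremental cost (GBP, 2010 price level) and mean
incremental effect (life-years or QALYs) reported by an economic
evaluation for a target country, from a base-case, subgroup, or
sensitivity analysis.  Estimates are clustered in studies and in
countries.  The model is a correlated pair of linear regressions with
random intercepts at the country, study, and data levels:

    y_di(jk) = β_0d + β_1d' x1_di + β_2d' x2_dj + β_3d' x3_dk
               + v_dk + u_dj + e_di          for d = 1 (ΔC), 2 (ΔE)

with bivariate-normal error terms per level:

    (v_1k, v_2k) ~ BVN(0, Ω_v),  (u_1j, u_2j) ~ BVN(0, Ω_u),
    (e_1i, e_2i) ~ BVN(0, Ω_e).

Only intercepts vary randomly; slopes are fixed across studies and
countries.  The bivariate form recognises the ΔC–ΔE correlation, lets the
two equations carry different covariates, and avoids committing to a
willingness-to-pay threshold λ.  It is implemented by stacking: each
estimate contributes a ΔC row and a ΔE row with response-indicator
columns, so the "bivariate three-level" model is mechanically a
univariate model with one extra dummy lowest level.

Three structures are supported.  **Cross-classified**: studies and
countries are crossed classifications (a multinational study's estimates
keep their per-country blocks, one u_j shared across blocks).
**Hierarchical**: strict nesting, requiring one country per study; data
from multinational studies are excluded.  **Hybrid**: all data retained,
but multinational-study estimates are reassigned to one pooled
country-level group ("MULTI"), so multinational information contributes
at the data and study levels without entering the between-country
comparison.

### Statistics of interest

The variance partition coefficient for response d at the country level is
VPC_vd = σ²_vd / (σ²_vd + σ²_ud + σ²_ed), with analogous study and data
shares; shares are reported in percent and sum to 100 per response.
Published variance-component tables in this literature print per-level
components on the **standard-deviation scale**; `cemeta` stores true
variances/covariances internally and squares printed components when
reproducing tabled VPCs — the squared ratio reproduces the printed VPC
percentages, the unsquared one does not.

Model fit is compared by the deviance information criterion with level-1
focus: D(θ) = −2 log p(y | β, v, u, Ω_e) conditions on the random
effects, Dbar is the posterior mean deviance, pD = Dbar − D(θ̄) at the
posterior means, DIC = Dbar + pD.  Differences of 1–2 points are treated
as the smallest worth acting on.  DIC values are not comparable between
models fitted to different data subsets (the hierarchical structure), and
`compare_structures` flags this.

## Estimation

All full conditionals are conjugate, so estimation is a pure Gibbs
sampler: multivariate-normal draws for β (GLS form under Ω_e and the
normal prior), independent bivariate-normal draws per cluster for v_k and
u_j, and inverse-Wishart draws for each Ω (df₀ + m, scale S₀ + Σ r rᵀ
over the level's m effects or the N data residual pairs).  Two additional
conjugate *translation moves* (generalised Gibbs updates along the
translation group) are interleaved, because the plain scan mixes very
slowly along two additively confounded directions:

* intercepts vs. the mean of each level's effects (the likelihood only
  identifies their sum): a shift δ with u_j → u_j + δ, β₀ → β₀ − δ is
  sampled from its Gaussian conditional;
* on nested data, country effects vs. their studies' mean effects:
  per-country shifts between v_k and {u_j : j ∈ k}.

Both moves leave the likelihood invariant, have unit Jacobian, and sample
from exact Gaussian conditionals, so the stationary distribution is
unchanged — they are extra Gibbs updates, not a reparameterization of the
model.  In testing they raised effective sample sizes for intercepts and
country-level variances by one to two orders of magnitude, and the
sampler's posterior moments match closed-form oracles (single-level
normal–inverse-Wishart; pinned-covariance GLS) to Monte-Carlo error in
both mean and spread.

Each chain has its own stream spawned from (seed, chain index); runs are
bit-reproducible.  Defaults: 2 chains, 2,000 burn-in, 10,000 stored
sweeps — chosen for desk-scale runtime; convergence should be checked per
fit with `diagnostics` (split-Rhat, ESS; parameters with Rhat > 1.05 are
flagged).  A level with fewer than two clusters cannot support a free
covariance matrix; the sampler refuses and asks for that level's Ω to be
pinned (pinning to zero removes the level).

### Priors

Coefficients get independent normal priors with mean 0 and variance
10⁶ × the sample variance of their response — i.e. precision 10⁻⁶ in
response-scale units.  An *absolute* prior variance cannot be diffuse for
both responses at once: costs in GBP and effects in life-years differ in
scale by four orders of magnitude, and a fixed N(0, 10⁶) prior would
visibly shrink cost coefficients (verified against a GLS oracle).

Covariance matrices get inverse-Wishart priors with df = 3 (the smallest
integer df giving a proper prior for 2×2 matrices) and scale df × an
ANOVA-type moment estimate of the level's covariance (covariance of
per-cluster mean OLS residuals; within-study-centred residual covariance
at the data level), falling back to the identity when the estimate is
unavailable or not positive definite.  The moment step serves as the
frequentist warm start for both the prior scales and the chain
initialisation.

## Preprocessing

Costs are standardised to GBP at 2010 prices before modelling:
legacy Eurozone currencies are first converted to EUR at their
irrevocable fixed rates, amounts are inflated from the reporting price
year to 2010 with country-specific GDP-deflator indices, and converted to
GBP with purchasing-power parities.  Conversion tables are user-supplied
inputs, not bundled.

Continuous covariates are grand-mean centred over estimates (study- and
country-level values broadcast first), so intercepts are predictions at
the average reported analysis.  Categorical covariates use reference-cell
indicator coding; "mixed sample"/"unclear" levels are ordinary levels.
Under the hybrid structure, a continuous country covariate for the pooled
group is filled with the unweighted mean of the member countries' values
(configurable), so country-covariate scans can run on all structures.

## The synthetic evidence base

No statin evidence base is redistributable, so `default_statins_config`
emulates the documented shape of that literature: 23 countries; 67
studies of which 6 are multinational (8 countries each from a pool of 16,
of which 6 countries appear only in multinational studies; single-country
studies cover 17 countries); 2,094 estimates of which 288 come from
multinational studies.  Level-wise standard deviations are set to the
variance components estimated from that literature's hierarchical
variance-components model — ΔC: country 5107, study 8564, data 10936
(2010 GBP); ΔE: 0.381, 0.564, 0.501 — implying country VPCs of 11.91%
(ΔC) and 20.32% (ΔE).  The ΔC–ΔE correlation of the random effects is not
reported; it is fixed at 0.25 at every level (mild positive coupling, as
expected when more effective strategies cost more).  Covariate generators
match the reported raw means/SDs (e.g. total cholesterol 6.676 (1.204)
mmol/L, SBP 137.48 (13.348) mmHg, intervention cost 528.84 (326.32)) and
category frequencies (age band 56–65: 41.17%, male: 38.16%, ...), drawn
independently per estimate.

Multinational studies share one study effect u_j across their country
blocks, and by default in the statins configuration their blocks carry
**no country effect** (`multinational_pooled_protocol=True`): a shared
protocol and common data sources homogenise multinational results across
countries.  This is the mechanism behind the headline structural
contrast: the hybrid model quarantines the homogeneous multinational data
in a pooled group and keeps a large country VPC, while the
cross-classified model attributes that homogeneity to the member
countries and deflates Ω_v.

What the generator does *not* emulate: covariate effects on (ΔC, ΔE) in
the default configuration (fixed part is intercept-only; planted-effect
tests add them explicitly), correlated covariates, publication-bias or
study-genealogy dependence between studies, unequal reporting of ΔC/ΔE,
and heavy-tailed or skewed residuals.  Passing recovery tests therefore
show that the machinery is calibrated under its own assumptions, not that
those assumptions hold for real evidence bases.

## Workflow conventions

`sequential_build` adds covariate blocks bottom-up (patient/disease →
intervention/comparator → methods), keeps a block only when its surviving
covariates are significant at 10% (posterior mean/SD normal score), carry
any declared expected sign, and lower DIC by at least 2; accepted steps
therefore have non-increasing DIC.  `scan_country_covariates` tests
country covariates one at a time (both equations by default) against the
multivariate base model with a shared seed; candidates missing or
constant over in-model countries are flagged, not fitted.

## Numerical choices and limitations

* Ω draws are checked symmetric positive definite (2×2 determinant test)
  at every stored sweep; a non-finite state aborts with the sweep index.
* Significance stars use the posterior normal score (mean/SD), two-sided
  at 10/5/1% — a pragmatic analogue of SE-based stars.
* Equal-tailed 95% posterior intervals throughout.
* The conditional (level-1 focus) DIC is only weakly sensitive to
  country-level covariates: the free country effects absorb between-country
  differences whether or not the covariate is present, so ΔDIC for a true
  country covariate is small (typically 0 to −2 at desk scale) even when
  its coefficient is decisively significant.  Detection in scans should
  rest primarily on coefficient significance and sign.
* ΔE pools life-year- and QALY-based estimates in one response; the
  effect-metric flag is available as a study covariate but no rescaling
  is applied.
* Estimates are unweighted: published cost-effectiveness estimates rarely
  come with usable precision, so studies reporting more sensitivity
  analyses carry more data rows (mitigated, not removed, by the study
  random effect).

## Problem sizes used in the automated checks

The test suite runs the heavy statistical checks at reduced scale:
parameter recovery uses 30 simulate-and-refit replicates of 20 countries
× 60 studies × ~2,000 estimates with 700-draw single chains; the
pooled-multinational mechanism check uses 20 replicates at the full
statins-like size (2,094 estimates) with 600-draw chains; conjugate and
effective-parameter oracles use 10,000-draw chains.  These sizes are the
package's own desk-scale choices; rerunning with longer chains or more
replicates sharpens, but has not changed, the conclusions.
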