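# Methods

## The model

A replicated RIL (recombinant inbred line) population carries genotypes
codable as Z ∈ {+1, −1} per line × marker (the two parental classes; the
lines are effectively homozygous).  For record *j* (line × replicate
plot, after plot-mean adjustment) the trait model is

    y_j = β + Σ_k Z_jk γ_k + Σ_{k'<k} Z_jk Z_jk' γ_kk' + ε_j,
    ε_j ~ N(0, σ²)

with one main effect γ_k per marker and, in the epistatic model, one
interaction effect γ_kk' per unordered marker pair (the pair's design
column is the elementwise product of its parents' ±1 columns).  For m
markers the epistatic model has m(m+1)/2 effects — 3240 for the 80-marker
map packaged here — fitted **simultaneously** to n records (378 in the
reference design of 126 lines × 3 plots).

Plot (block) effects are removed beforehand by subtracting each plot's
mean from its records; all records enter the plot means.

## Empirical Bayes shrinkage

Each effect receives a normal prior γ_k ~ N(0, σ_k²) with its own
variance component, and each σ_k² a scaled inverse chi-square hyperprior
Inv-χ²(τ, ω).  The default (τ, ω) = (−2, 0) makes that hyperprior flat,
p(σ_k²) ∝ 1; other values can be selected by the built-in leave-one-out
hyperparameter search.

The fit is iterative conditional-mode empirical Bayes.  Writing
V = ZDZ' + σ²I for the marginal covariance (D = diag σ_k²), a sweep
visits every term once and uses its marginal posterior moments

    γ̂_k = σ_k² Z_k' V⁻¹ (y − β),      V_k = σ_k² − σ_k⁴ Z_k' V⁻¹ Z_k,

to update σ_k² ← max(floor, (γ̂_k² + V_k + ω)/(τ + 3)); with the flat
hyperprior this is γ̂_k² + V_k.  β is re-estimated by GLS and σ² by its
EM update once per sweep.  Each σ_k² change is folded into V⁻¹ by a
rank-one Sherman–Morrison update, and because replicate records share
their line's design row, all per-term algebra runs on the line-level
aggregation R'V⁻¹R (126 × 126 for the reference design), which is what
makes a sweep over all 3240 epistatic terms take a fraction of a second.

The iteration is a monotone ECM ascent of the marginal posterior (β and
σ² are M-steps; each σ_k² update maximises the expected complete-data
log posterior given the marginal posterior of γ_k).  Its fixed points
satisfy σ_k² = γ̂_k² + V_k — visible in the published estimates this
package ships, where the printed per-term variance equals effect² +
StdErr² to print precision.  The reported standard error is the
posterior sd √V_k, and the Wald statistic W = γ̂_k²/V_k feeds

    p = 1 − F_χ²(1, W),      LOD = W / (2 ln 10).

### Numerical choices

- **Initialisation** (deterministic — no randomness anywhere in the fit):
  all σ_k² at 1e−4 · var(y), σ² at var(y), β by GLS.
- **Variance floor**: σ_k² is clamped at 1e−12 · var(y) (configurable)
  instead of exactly zero so posterior sds stay defined; floored terms
  report effects numerically indistinguishable from zero.  Constant
  (monomorphic) design columns — which arise naturally as products of
  co-located markers — are pinned at the floor and flagged.
- **Convergence**: maximum relative change of any variance component
  below `rel_tol` (default 1e−8), or `max_sweeps` (default 200).  Null
  terms decay toward the floor only algebraically (σ² ∝ 1/sweep), so
  large problems typically stop at the sweep cap; effect ranking and the
  large effects stabilise within a few tens of sweeps, which is why the
  test suite and acceptance runs cap sweeps at 40–100 and say so.
- **Fixed-variance solves** use two algebraically identical routes
  chosen by shape: a p × p ridge normal-equation solve when p ≤ n_lines
  (stable for arbitrarily large σ_k², e.g. the OLS limit), otherwise the
  line-level Woodbury route (stable for the bounded variances the EB
  iteration produces).
- The objective `marginal_log_posterior` profiles β by GLS and adds the
  unnormalised hyperprior log density (identically zero at (−2, 0)); on
  instances with ≤ 3 terms the converged fit matches or beats a fine
  independent grid search of this objective to 1e−4.

## Effect ranking and cross-validation

Terms are ranked by decreasing LOD; ties break toward the larger
absolute effect, then canonical term order.  Leave-one-**line**-out CV
grows the prediction model along that ranking: for each candidate size
m\* and each fold, the top-m\* terms are refitted from scratch on the
training lines and the held-out line's records are predicted as
ŷ = β̂ + Σ Z γ̂.  The curve statistic

    r² = 1 − SSE/(SSE + SSRp),  SSE = Σ(y−ŷ)²,  SSRp = Σ(ŷ − mean ŷ)²

is the proportion of phenotypic variance carried by the predictions (not
a squared Pearson correlation); it is bounded in [0, 1], equals 1 at a
perfect fit and 0 for constant predictions.  The centring mean is that
of the predictions by default (a switch allows the mean of the
observations; on real curves the two differ negligibly because the
intercept of a plot-mean-adjusted trait is ≈ 0).

Two ranking scopes exist:

- **Study mode (default)**: LOD ranking computed once from the full-data
  fit, held fixed across folds.  This mirrors the source analysis and is
  deliberately optimistic — the held-out line influenced which terms are
  eligible — which inflates the tail of the curve and pushes its argmax
  rightward.
- **Honest mode** (`rank_per_fold=True`): each fold re-ranks on its own
  training lines.  Null-trait curves then stay near zero and
  planted-signal curves show a genuine peak near the true model size.
  The CV acceptance checks run in this mode for exactly that reason.

Within a fold the selected subset is fitted in canonical term order —
membership, not inclusion order, defines the model — so the ranked and
random-inclusion curves coincide exactly at full model size.  Ties in
the argmax resolve to the smallest size (parsimony).  The random
baseline requires an explicit seed and defaults to a single order.

## The synthetic world

No genotype/phenotype data are deposited for the motivating soybean
somatic-embryogenesis study, so the generator recreates its stated
design: 126 F5:6 lines, 3 replicate plots (378 records), and the
published 80-marker SSR map (77 markers on 19 linkage groups + 3
unmapped) shipped verbatim — including its unusually large printed cM
spans, reproduced without reinterpretation, and its co-located marker
pairs, which yield perfectly correlated columns and monomorphic product
columns downstream.

Genotypes follow a Markov chain along each linkage group: first marker
±1 with probability ½, adjacent markers recombining with the selfed-RIL
probability R = 2r/(1+2r), r = (1 − e^(−2d/100))/2 (Haldane, d in cM).
Linkage groups and unmapped markers are independent; residual F5:6
heterozygosity is ignored to match the two-class coding.  Traits are
generated from the fitted model itself: line genomic value plus one
Gaussian block effect per plot plus iid Gaussian noise.  A Poisson count
mode (log link, each record averaging 10 simulated plants) exists behind
a flag but is excluded from acceptance checks, mirroring the side
analysis the source reported only qualitatively.

Defaults not fixed by the study design were chosen once as a plausible
field trial and not revisited: trait mean β = 10 (a count-scale mean),
sparse architectures of 3 main + 3 epistatic effects with magnitudes
uniform in [0.5, 1.0] and random signs, plot-effect sd 1.0 and residual
sd 1.5 — giving broad-sense heritabilities around 0.5–0.7, strong enough
that recovery is expected but with realistic noise.  What a green test
establishes is therefore that the estimator recovers architectures of
this kind under linkage; the generator does not emulate genotyping
error, segregation distortion, missing data (rejected at input, not
imputed), crossover interference, or count-valued noise in the default
path.

## Known limitations

- The sweep cap, not `rel_tol`, is the effective stopping rule for
  p ≫ n problems (see above); `converged=False` with a logged warning is
  the expected outcome there and is non-fatal by design.
- The method is practical up to roughly 60 effects per record (the
  regime its source validated); beyond that a warning is logged and
  estimates may degrade.
- Recomputing LOD from estimates printed to 4 decimals reproduces a
  printed 2-decimal LOD only to ~0.2–0.6% relative at LOD ≳ 20; the
  packaged-table consistency tests account for that rounding envelope.
- h, the per-term proportion of phenotypic variance, is reported as
  σ̂_k² · var(Z_k)/var(y) — a documented convention, as the source
  defines no formula for its printed column.
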