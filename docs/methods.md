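# Methods and modelling notes

## Model

Haploid, asexual, effectively infinite population of two distinct types —
cooperators (C) and defectors (D) — interacting in groups of fixed size
`n ≥ 2`.  Fitness depends only on own type and the number `i` of
cooperators in one's group (focal included): `pi_C(i)` for `i = 1..n`,
`pi_D(i)` for `i = 0..n-1`.  The two corner values `pi_C(0)` and
`pi_D(n)` do not exist and the containers refuse to produce them.

A population structure is a map `p -> (f_0(p), ..., f_n(p))` from the
overall cooperator frequency to group-type frequencies, with
`sum_i f_i = 1` and `sum_i (i/n) f_i = p`.  No dynamics on `f` itself is
modelled: the structure is a constraint surface along which the
population state moves as `p` changes.  Generations do not overlap and
groups re-form each generation according to `f`.

### Endpoint profiles and invasion

The composition distribution experienced by a rare cooperator at `p = 0`
is `u_i = lim (i/n) f_i(p)/p`, and by a rare defector at `p = 1` is
`ubar_i = lim ((n-i)/n) f_i(p)/(1-p)`.  These limits, not any single
relatedness number, decide invasion: cooperators invade iff
`sum u_i pi_C(i) > pi_D(0)` (strict; ties are flagged neutral and treated
as non-invasion).  Interior states use the conditional distributions
`vC_i = (i/n) f_i(p)/p` and `vD_i = ((n-i)/n) f_i(p)/(1-p)`.

### Relatedness

`r(p) = P(C|C) - P(C|D)`, with `P(C|C) = sum_i vC_i (i-1)/(n-1)` and
`P(C|D) = sum_i vD_i i/(n-1)`.  At the boundaries the profile replaces
the conditional distribution; the p = 0 sum runs over all `i = 1..n`
(profiles can carry mass at `i = n`, e.g. clonal structures, and `r = 1`
requires including it).

### Counterfactual costs and benefits

For a cooperator at composition `i`, the switch effects are
`c_i = pi_D(i-1) - pi_C(i)` and
`b_i = (i-1)[pi_C(i) - pi_C(i-1)] + (n-i)[pi_D(i) - pi_D(i-1)]`; a
defector at composition `i-1` switching to cooperation has the identical
counterfactual pair.  Population-level `c(p), b(p)`:

* **p = 0**: the resident background's lone switch, `(c_1, b_1)` —
  `c = pi_D(0) - pi_C(1)`, `b = (n-1)[pi_D(1) - pi_D(0)]`.  With `r` from
  `u`, `rb - c` is then an exact rewriting of the boundary inequality
  `sum_i u_i {pi_C(1) + (i-1)[pi_D(1) - pi_D(0)]} > pi_D(0)`.
* **p = 1**: symmetrically `(c_n, b_n)`.
* **interior p**: the expectation of `(c_i, b_i)` over a conditional
  composition distribution.  The default averages over cooperators
  (`vC`); `defectors` and `population` (the p-weighted blend, which
  interpolates the two boundary conventions continuously) are available
  behind the same contract.  For non-linear fitness these conventions
  differ — the interior definition is genuinely open, which is why it is
  isolated in one function (`SelectionAnalysis.population_cb`) with the
  rule as an explicit argument.  All equilibrium and violation-map
  numbers reported by this package use the cooperator convention.

Under equal gains from switching (both payoff schedules linear with a
common slope) `c_i` and `b_i` are constants and `rb - c = S(p)` exactly,
for every structure, every `p`, every averaging rule — the property
suite asserts this at 1e-10.

### Synergy conditions and the violation road map

1. `pi_C(i) >= pi_C(1) + (i-1)[pi_D(1) - pi_D(0)]` for all `i`;
2. `pi_D(i) >= pi_D(n-1) - (n-i-1)[pi_C(n) - pi_C(n-1)]` for all `i`;
3. `S(p)` non-decreasing in `p`.

Conditions 1 and 2 are properties of the fitness function alone and are
checked algebraically; condition 3 depends on the structure and is
checked on an evenly spaced grid (default 101 points) — non-monotonicity
hiding strictly between grid points is accepted risk.  Equal gains (1 and
2 with equality, tolerance 1e-9) means no violation is possible anywhere;
all three conditions mean violations can occur only out of equilibrium;
otherwise in-equilibrium violations are possible.  The first two
implications are theorems (tested on 1000 random instances); the verdict
in the remaining case says "possible", not "present".

## Numerical choices

* **Equilibria**: `S(p)` is scanned on a 1001-point grid; sign changes
  are refined by Brent's method (`xtol` 1e-14); a root requires
  `|S| <= 1e-10`; stability is read from the sign of `S` half a grid step
  to either side (+ to − means stable).  Grid nodes already within the
  root tolerance are root candidates; duplicates within 1e-9 are merged.
  `max|S| <= 1e-9` over the grid flags a degenerate (neutral) system with
  a warning and no roots.
* **Violation accounting**: a stable interior equilibrium with
  `|rb - c| > 1e-8`, or a stable boundary whose `rb - c` sign opposes the
  realised invasion outcome, counts as an in-equilibrium violation.
* **Endpoint limits** for custom structures: the quotient is evaluated at
  `p = 1e-3, 5e-4, 2.5e-4, ...` with one-step Richardson extrapolation
  (`2 g(eps/2) - g(eps)`), declared converged when successive
  extrapolants agree to 1e-7; this assumes one-sided differentiability of
  `f` at the boundary (all built-in families are polynomial).  Built-in
  families carry closed-form profiles; the numerical path agrees with
  them to 1e-6 (tested) and serves as their independent check.
* **Tolerances** live in one frozen `Tolerances` object
  (`hamrule.config`), overridable per analysis.

## Structure families

`constant_r_2player` and `clonal_or_binomial` (clonal with probability
`r`, binomial otherwise; constant relatedness `r` for any `n`; the two
coincide at `n = 2`).  `mixture` takes convex combinations — the
constraints are linear in `f`, so validity and profiles combine linearly.
`endpoint_profiles` manufactures a valid structure for a requested
`(u, ubar)` pair by crossfading, with weight `w(p) = p^2(3-2p)`, between
two piecewise-linear structures pinned to the requested boundary
compositions; because `w = o(p)` and `1-w = o(1-p)`, the boundary limits
are exactly the requested profiles, and because each pinned primitive is
itself a valid structure at every `p`, the whole path is valid.  The
interior path is an arbitrary representative of the many structures
sharing those endpoints and is flagged as such in the object's metadata;
only boundary behaviour is contractual.  Realizability of arbitrary
`(u, ubar)` pairs by *some* structure is guaranteed only for what this
construction covers.

## Worked examples and their profiles

The four n = 10 games use payoffs `base + 2 (i/n)^k` with `k = 1`
(equal gains), `2` (synergy) and `0.5` (anti-synergy).  The endpoint
profiles shipped with them are minimal-support reconstructions, moment-
matched to the known boundary selection differentials: the linear games
constrain only `E[i]` (weights 0.64/0.36 on i = 1/2, and 0.2/0.8 on
i = 2/3), the quadratic game only `E[i^2]` (0.45/0.30/0.25 on i = 2/3/4),
with mirror symmetry `ubar_i = u_{n-i}`.  They are synthetic stand-ins
for a fully specified assortment process, adequate exactly because the
boundary quantities they feed depend on those moments alone.  The
anti-synergy n = 10 game ships without profiles; its mixed-equilibrium
behaviour is exercised through the 2-player anti-synergy game, where
everything is available in closed form.

## Regression engine conventions

* Partner traits are aggregated per relationship class by the arithmetic
  mean (option: sum), keeping `b_k` interpretable as the benefit of a
  fully cooperative class and comparable across class sizes.
* Fitness is treated as offspring count with faithful transmission
  (offspring copy the parental trait), so the one-generation change in
  mean cooperativeness is `delta_xbar = cov(w, x_se)/mean(w)` with no
  transmission term; covariances are population covariances (ddof 0).
* The bookkeeping identity is
  `delta_xbar = (var(x_se)/mean(w)) (sum_k r_k b_k - c)`.  The popular
  shorthand `delta_xbar = rb - c` drops the positive factor
  `var(x_se)/mean(w)`; results objects store the factor and the residual
  explicitly, and the guaranteed statement is sign equivalence.
* The OLS primitive solves the normal equations after a column-pivoted QR
  rank check (rank-deficient designs raise an error naming the offending
  columns); residual-regressor covariances are certified below 1e-10.
  Nested-model comparisons go through statsmodels' F test, which also
  cross-checks the design construction in the unit tests.
* Model choice between specifications is by nested F tests at a
  configurable alpha (default 0.05); non-linear terms (interactions,
  quadratics) are first-class regressors so that the *absence* of
  non-linearity can be tested rather than assumed.
* `estimate_pi_from_groups` estimates payoffs as composition-cell means
  and tests generalized equal gains by comparing the saturated cell-mean
  model against the 3-parameter additive model
  `w = a + g 1{C} + d (cooperating partners)` — exactly the family for
  which the counterfactual rule is structure-independent.

## Synthetic data: what it does and does not emulate

`sibling_population` draws a binary focal trait and partner traits that
copy it with probability equal to the pedigree relatedness, with linear
(optionally interacting/quadratic) Gaussian-noise fitness.  It emulates
cross-sectional trait/fitness sampling with known pedigree classes; it
does not emulate overlapping generations, measurement error in traits,
non-Gaussian fitness, indirect genetic effects, or class-size
heterogeneity.  Passing tests therefore certify the estimators' algebra
and calibration under clean sampling, not robustness to those real-data
complications.  `group_records` emulates a composition-design experiment
with i.i.d. Gaussian fitness noise per individual.

The spurious-violation simulation contrasts `rb - c` evaluated with the
in-sample phenotypic relatedness (which cannot disagree with the realised
direction of selection) against the same expression with the pedigree
relatedness plugged in.  Because both evaluations share the estimated
`b` and `c`, their signs are positively correlated; the disagreement
fraction at small samples is therefore well below one half even when the
true `rb - c` sits on the boundary (~0.22 at n = 20 under the default
configuration), and it decreases toward zero as samples grow.

## Stochastic suite design

Effect sizes and sample sizes were fixed by a-priori power analysis: an
interaction coefficient of 1.5 (comparable to the main effects b = 2,
c = 0.8) at sigma = 1 and n = 200 puts the nested-F power near 0.99;
payoff curvature `0.02 i^2` against sigma = 0.1 with 50 observations per
cell makes the equal-gains test's power effectively 1.  Calibration
checks use 1000 replicates (Monte-Carlo SE 0.0069 at alpha = 0.05) and
assert agreement within 2 MC SEs; both F tests are exact under their
Gaussian nulls, so this is a coverage check of the implementation, not a
tuned threshold.  Replicate counts and grid sizes throughout were chosen
to keep the full suite around a minute on one core while leaving the
Monte-Carlo bands meaningful.

## Known limitations

* Continuous within-group frequencies (the large-`n` limit) are not
  implemented; large `n` discrete games approximate them.
* The interior-`p` counterfactual cost/benefit convention is one of
  several defensible choices (see above); results at interior equilibria
  depend on it, boundary results do not.
* Condition 3 and equilibrium detection are grid-based; pathological
  structures with features finer than the grid can evade them.
* The regression engine assumes faithful transmission and one focal
  record per individual; diploid genetics, GLS error structures and
  marker-based relatedness estimation are out of scope.
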