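# hamrule

**Can Hamilton's rule disagree with the direction of selection — and when
could you ever observe it?**  `hamrule` is a toolkit for social-evolution
theory and for the design of empirical tests of Hamilton's rule
(*rb > c*).  It evaluates, exactly and at desk scale, both of the ways
costs and benefits are defined in the literature:

* the **counterfactual method** — *c* is what a focal individual would
  gain by switching to defection, *b* is the aggregate fitness change its
  switch causes in its group-mates — for cooperator/defector games in
  groups of size *n* under a general model of assortative group
  composition; and
* the **regression method** — *−c* and *b* are partial regression
  coefficients of fitness on own and partners' cooperativeness, with
  relatedness cov(*x*ₖ, *x*ₛₑ)/var(*x*ₛₑ) — for individual-level
  trait/fitness records.

## The model

A population of cooperators (C) and defectors (D) interacts in groups of
size *n*.  Payoffs are π_C(*i*) for a cooperator and π_D(*i*) for a
defector in a group containing *i* cooperators (focal included).  A
*population structure* is a family *f*ᵢ(*p*) of group-type frequencies at
overall cooperator frequency *p*, constrained by Σᵢ *f*ᵢ(*p*) = 1 and
Σᵢ (*i*/*n*) *f*ᵢ(*p*) = *p*.  Its boundary behaviour is captured by the
*population structure profiles*

u_i = lim_{p→0} (i/n) f_i(p)/p,    ū_i = lim_{p→1} ((n−i)/n) f_i(p)/(1−p),

the group-composition distributions experienced by a rare cooperator or a
rare defector.  Cooperators invade iff Σᵢ u_i π_C(*i*) > π_D(0);
relatedness is r = P(C|C) − P(C|D).  Hamilton's rule with counterfactual
costs and benefits is exact for every structure when fitness shows *equal
gains from switching* (linear payoffs); with synergies it can fail out of
equilibrium only; with anti-synergies a population can sit at a stable
mixed equilibrium where selection is neutral yet *rb − c* ≠ 0 — an
in-equilibrium violation.  With regression-defined costs and benefits the
Price/OLS identity makes the rule hold for any linear specification, so
apparent empirical violations must come from elsewhere (e.g. the
discrepancy between phenotypic and pedigree relatedness estimators, which
the package simulates).

## Worked example

An anti-synergy prisoner's dilemma (π_C(1)=1.9, π_C(2)=3, π_D(0)=2,
π_D(1)=4.9) under a 2-player structure with constant relatedness r = 0.3:

```python
import hamrule as hr

game = hr.antisynergy_game()
an = hr.SelectionAnalysis(hr.constant_r_2player(0.3), game.to_fitness())
for e in an.find_equilibria().equilibria:
    print(f"p* = {e.p:.5f}  ({e.stability})  rb - c at p* = {e.hr:.3f}")
_, summary = an.violation_map(201)
print("in-equilibrium violation:", summary.in_equilibrium_violation)
```

prints

```
p* = 0.18254  (stable)  rb - c at p* = -0.231
in-equilibrium violation: True
```

The population settles at a stable mix of 18% cooperators (the root of
S(p) = 0.23 − 1.26 p), where the average counterfactual cost is 0.87 and
the aggregate benefit 2.13, so rb − c = 0.3·2.13 − 0.87 = −0.231:
Hamilton's rule says cooperation should shrink, selection says it is
exactly neutral.  The regression method, by contrast, can never disagree:

```python
data = hr.sibling_population(seed=1, n_individuals=400)
res = hr.HamiltonRegression.from_dataframe(data, hr.Specification.II()).fit()
print(res.summary())
```

```
Regression-method Hamilton's rule
================================================
specification: II (linear)
observations:  400
...
cost c            = 0.827599
benefit b[sib]   = 2.024877   relatedness r[sib] = 0.464912
benefit b[cou]   = 0.333211   relatedness r[cou] = 0.188471
sum r_k b_k - c   = 0.176592
delta xbar        = 0.009030
identity residual = -6.765e-17
```

The identity residual is the gap in
Δx̄ = (var(x_se)/w̄)(Σₖ rₖbₖ − c); it vanishes to machine precision for
*every* linear specification — the sense in which the regression-method
rule is unfalsifiable.

A console script exposes the same operations
(`hamrule classify`, `hamrule equilibria`, `hamrule scan`,
`hamrule regress`, `hamrule estimate-pi`, `hamrule simulate-spurious`,
...); see `hamrule --help`.

## Layout

- `hamrule.fitness` — payoff tables, counterfactual switch effects,
  synergy diagnostics
- `hamrule.structures` — structure families, validation, endpoint
  profiles (closed-form and numerical limits)
- `hamrule.selection` — `SelectionAnalysis`: invasion, relatedness,
  rb − c, equilibria, violation maps, constant-r scans
- `hamrule.regression` — `HamiltonRegression` model/results, nested-F
  non-linearity test, payoff estimation from group records
- `hamrule.simulate` — seeded synthetic populations and the
  spurious-violation simulation
- `hamrule.examples` — the worked games and reconstructed profiles
- `docs/methods.md` — modelling assumptions, conventions and numerical
  choices
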