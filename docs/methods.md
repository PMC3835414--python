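# Methods

`famgroups` simulates the coevolution of a socially learned cooperative-
breeding trait and a genetically inherited quality trait in a population of
human family groups.  This note records the model, its parameters and
defaults, the reasoning behind the numerical and design choices that were
genuinely open, and what the synthetic populations do and do not represent.

## The model

Agents are individuals with sex, integer age (0–100), a heritable genetic
quality q ∈ [0, γ], and — from age 18 — a fixed binary cooperativity trait.
They live in family groups, one group per territory (patch).  Children
(age < 18) are attached to their mothers; adults (18–49) may marry and
reproduce; elders (50+) no longer reproduce but keep producing resources and
face rising mortality; death at 100 is certain.

Each year five stages run in fixed order:

1. **Matchmaking.**  Unmarried 18–49-year-olds are randomly paired across
   groups (one proposal per agent per year).  Agent *i* accepts candidate
   *j* with probability q_j^s(age_i), where the choosiness exponent
   s(age) = s₀ · max(0, (49 − age)/31) declines linearly from s₀ = 3 at age
   18 to 0 at 49, so older agents accept mates of any quality.  On mutual
   acceptance the couple marries and the dispersal-sex spouse (female by
   default) moves to the partner's group, dependent children in tow.  A
   marriage is blocked if it would push the receiving group past the
   carrying capacity K.
2. **Family fissioning.**  A group larger than K/2 splits onto a free patch
   if one exists (patches free up when a group dies out).  Married couples
   split as units, unmarried adults and elders are halved at random within
   each class-by-sex cell, and children follow their mothers.
3. **Resource contribution.**  An adult of age a and quality q can collect
   r = (0.5 + 0.5 q) · R · tent(a) resources, where the tent profile rises
   from 0.5 at 18 to 1 at 50 and declines to 0.2 at 100.  A patch yields at
   most Y resources per year: the cap binds on the group's summed
   age-profile gathering effort (scaled pro rata), while quality scales what
   each individual makes of its share — so crowded territories yield less
   per head, and a poorly adapted group extracts less from the same
   territory than a well-adapted one.  This, not the headcount cap K, is
   what limits a well-provisioned group's size.
   Cooperators donate 90% of their collection to the group
   pool, defectors 10%.  The pool is divided equally among the group's
   married 18–49 females; each such female's childrearing budget is her own
   retained production plus her share.  Mothers outside the recipient set
   (widows, elder mothers of minors) can spend only their own retained
   production on their children; all other retained resources play no
   further role.  Budgets do not carry over between years.
4. **Childbirth, childrearing, child death.**  Supporting a child of age a
   costs β′ · exp(−a/τ) this year, where β′ is the year's effective cost of
   childrearing and τ = 1.5 y: care is heavily front-loaded, and a newborn
   costs the full β′ (the cost of giving birth).  While a mother's budget
   cannot cover her brood, her youngest child starves, oldest-first
   survivors being the maximal affordable set.  If the residual then covers
   β′ and the group is below K, she bears one child (at most one per year);
   the newborn's quality is the mid-parent mean plus Normal(0, 0.05) error,
   clamped to [0, γ].  All children then face the mortality hazard.
5. **Adult aging and death.**  Adults face the hazard; orphans are adopted
   by a random married 18–49 female of their group or die if there is none;
   everyone ages one year; agents turning 18 adopt cooperativity with
   probability equal to the cooperator frequency among their group's
   trait-bearing members (unbiased transmission — equivalent to copying one
   group adult at random; frequency 0 and 1 are therefore absorbing).

The yearly hazard is m(a) · (1 + λ(1 − q)) capped at 1, with λ = 1 and m
piecewise geometric: 0.15 at birth decaying to 0.01 by age 5, flat to 50,
then rising geometrically to 1 at 100.

Environmental harshness enters three ways: the base cost of childrearing β;
a ceiling γ ≤ 1 on attainable genetic quality (with initial mean quality
γ/2), modelling migration into an environment the population cannot
genetically track; and yearly cost noise, β′ = max(0, β + Normal(0, σ_ν)),
drawn once per year and applied world-wide.  The floor at zero means that
for very low β the expected effective cost exceeds β.

## Parameters and defaults

| parameter | default | units | role |
|---|---|---|---|
| β (`beta`) | 50 | resources | base cost of childrearing = birth cost |
| γ (`gamma`) | 1.0 | – | ceiling on genetic quality |
| σ_ν (`sigma_nu`) | 0 | resources | SD of yearly cost noise |
| K | 300 | agents | patch headcount capacity |
| groups / patches | 50 / 50 | – | initial groups; patches = groups, so territory frees only on group extinction |
| initial group size | 40 | agents | 5 per sex × {child, unwed, parent, elder} cell |
| R (`peak_output`) | 100 | resources/yr | peak individual collection potential |
| Y (`patch_yield`) | 2600 | resources/yr | maximum yearly yield of one territory |
| quality floor | 0.5 | – | collection ∝ 0.5 + 0.5 q |
| τ (`decay_time`) | 1.5 | years | child-cost decay |
| donation fractions | 0.9 / 0.1 | – | cooperator / defector |
| mutation SD | 0.05 | – | quality transmission error |
| s₀ (`mate_choosiness`) | 3 | – | mate-acceptance exponent at 18 |
| initial q | Normal(γ/2, 0.24) clamped to [0, γ] | – | initial quality |
| initial cooperators | 0.5 | – | per-adult Bernoulli |

The "well-adapted" initialization draws quality as γ − |Normal(0, 0.175 γ)|,
a left-skewed distribution with mode γ and mean 0.86 γ, and 90% initial
cooperators.

### Why these resource-economy defaults

The resource scale is the one genuinely free part of the design, and three
constraints pin it:

- *Cooperative breeding must be necessary.*  At the yield-limited group
  equilibrium no mother — cooperator or defector — can cover even one
  newborn's cost at β = 50 from her own retained production, and the full
  (discounted) cost of rearing one child to adulthood, ≈ 2.05 β, exceeds
  any individual's yearly collection.  Mothers depend on the pooled
  contributions of their group.
- *The harshest printed condition must be viable for cooperative groups.*
  A group's pool share per mother is roughly (0.1 + 0.8 f) × Y-limited
  supply per recipient, where f is the group's cooperator frequency; R and
  Y are set so that at β = 100 only cooperator-rich groups sustain births
  (group-level selection), while at β = 25 even defector-heavy groups do
  (so within-group selection against cooperator mothers, who keep 10%
  instead of 90% of their own collection, dominates and the trait declines).
- *Resources, not headcount, must limit group size.*  Because the pool is
  split equally among recipients, per-mother shares are independent of group
  size; without a finite patch yield nothing stops a mild-environment group
  from saturating K, after which budgets go slack and the trait becomes
  selectively neutral.  The finite yield Y creates the interior group-size
  equilibrium (smaller groups in harsher years and under lower γ) that keeps
  budgets binding at every β.

These defaults were frozen after a coarse grid search over (R, Y) at 5–8
seeds per condition against the qualitative pattern the model is built to
exhibit — cooperator frequency rising with β, staying near or below its
initial value when costs are low, remaining bounded near 0.7 in the
harshest viable condition, and full survival at β = 50 — and then validated
on independent seeds.

## Problem sizes

Sweeps and the test suite run at desk scale: 30 family groups (initial
population 1200), carrying capacity 150, 10 replicates of 2000 years per
condition.  Both structural reductions are variants the model's results are
robust to (the robustness battery re-checks the orderings under 80 groups,
K = 300, and male dispersal).  The dynamics settle well inside that horizon: the early crash
and recovery under high β complete within a few hundred years, and terminal
statistics at 2000 years are stable.  The full scale of 50 groups and 50
replicates of 10⁴ years is available by passing `ModelParams()` and explicit
`n_runs`/`horizon`.

## Aggregation conventions

Trait and quality trajectories are averaged over surviving replicates only;
survival fractions count all replicates.  Terminal cooperator frequency is
computed over trait-bearing agents (adults and elders).  Monotonicity claims
are statistical (Spearman rank correlation at α = 0.05 across per-replicate
terminals).

## Numerical and tie-breaking choices

- All randomness flows through one `numpy.random.Generator` per run;
  replicate seeds derive from `SeedSequence([seed_base, stream, i])`.
  Identical seed + identical parameters ⇒ bit-identical runs.
- Starvation uses a 10⁻⁹ budget tolerance so exact-cost broods survive.
- Matchmaking pairs by random permutation with one rotation pass to repair
  same-group collisions; residual collisions simply get no proposal that
  year (a cheap near-maximal random cross-group matching).
- Within-stage ties (which candidate mothers take scarce birth slots under
  the K cap, which same-aged child starves first, fission cell remainders)
  are broken by the run RNG.
- Mortality draws use pre-increment ages; aging follows deaths.
- A maturing agent's trait probability is computed from the group state
  before any of that year's cohort bears the trait, so cohort-mates do not
  influence one another.

## Open design points, resolved

- **Orphans** (the source text is silent): children of a dead mother are
  adopted by a random married 18–49 female of the same group; failing that
  they die at the end of the year.  Adoption-within-group is the minimal
  rule consistent with children's lives being attached to their mothers in a
  model whose subject is alloparenting.
- **Remarriage**: widowed adults under 50 re-enter the matchmaking pool the
  next year; elders do not (they cannot reproduce).
- **Non-recipient mothers** spend their own retained production on their
  children (widowhood is thus costly, especially for cooperator mothers).
- **Fission keeps couples together** even though classes split evenly,
  avoiding long-distance marriages the model has no semantics for.
- **β′ is global**: the noise models climate shared by the whole population,
  not per-territory weather.
- **Stage-4 ordering**: resource allocation precedes the child hazard.

## What the synthetic populations are, and are not

All populations are generated internally; there is no empirical input.  The
generator reproduces the *structure* asserted for the study system — equal
sex ratios and age-class counts at initialization, unbiased within-group
social learning, egalitarian pooling to mothers — under stationary
environmental statistics.  Real foraging populations differ in ways the
model deliberately ignores: no wealth accumulation or inheritance, no
sex-biased learning, no punishment or institutional enforcement, no
short-timescale individual luck in foraging returns, no skewed or
catastrophic cost shocks (yearly noise is Gaussian), and no explicit kin
accounting beyond the mother and spouse links.  Passing tests therefore
show that the *mechanism* — group-level selection on a socially learned
helping trait under resource scarcity — behaves as described under these
idealized conditions, not that the calibrated numbers transfer to any real
population.

## Known limitations

- The life-history curves are qualitative stand-ins constrained at the
  level of shape and viability, not fits to demographic data.
- At desk scale the harshest conditions can lose every replicate for an
  unlucky calibration; survival fractions at β = 100 are sensitive to R and
  Y in a way terminal frequencies are not.
- Terminal trait frequencies in mild environments retain substantial
  between-replicate variance (the trait is nearly neutral there); claims
  about them are statistical, never per-run.
- Group-level selection operates through both extinction-recolonization and
  differential growth; the model does not separate the two channels.
- Because the trait is learned from the natal group's frequency rather than
  from the parents, differential fertility between cooperator and defector
  mothers cannot by itself change a group's trait frequency: a defector
  mother's extra children still adopt the group's frequency.  With no
  survival cost of cooperating (a deliberate exclusion), the model has no
  systematic within-group force pushing cooperation down.  In mild
  environments the trait is therefore nearly neutral — it hovers around its
  initial frequency rather than declining decisively — and in harsh
  environments the group-selected plateau relaxes only by drift.  A
  mortality cost for cooperating reproductive-age females would be the
  natural extension restoring a strong decline, at the price of an extra
  fitness term.
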