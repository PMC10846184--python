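# Methods

## Scope and model conventions

The package operates on stoichiometric metabolic models with flux bounds and
a biomass objective. Conventions, enforced at load time:

* Every exchange reaction consumes exactly one extracellular metabolite with
  stoichiometric coefficient −1; negative flux is uptake, positive flux is
  excretion. Exchanges are auto-detected when a model file does not list them.
* The compound id of an exchange is the id of its extracellular metabolite;
  diets, Biolog tables and class maps are keyed by these compound ids.
* A diet maps compounds to availabilities in mmol/L, applied *directly* as
  negated exchange lower bounds (the standard simplification when kinetic
  uptake parameters are unknown). Compounds absent from the diet are closed
  (lb = 0); designated micronutrients (e.g. Fe/Cu cations) are opened to
  −U_free so they never limit growth. U_free = 1000 mmol·gDW⁻¹·h⁻¹
  throughout: no stated magnitude exists for "non-limiting", so one value is
  used consistently for micronutrients, shuttle bounds and default reaction
  caps.

Model files use a small explicit JSON dialect (metabolites, reactions with
stoichiometry/bounds/objective, optional exchange list, biomass id) because
solver-specific model objects do not travel well; an SBML-L3/FBC subset can
be read through cobrapy when installed.

## Linear programming

Flux balance analysis maximizes `c·v` subject to `S·v = 0`, `lb ≤ v ≤ ub`,
solved with HiGHS (via scipy) at tightened feasibility tolerances (1e-10).
The flux-sum-penalized variant maximizes `c·v − ε·Σ|v_r|` with ε = 10⁻⁶ by
default, implemented by splitting reversible reactions into non-negative
forward/reverse parts in a single combined objective (not a lexicographic
two-stage solve). The penalty covers *all* reactions, exchanges included; a
sensitivity check on the toy networks shows the selections are unchanged if
exchanges are excluded, since ε is six orders below the growth terms. The
reported objective of a penalized solve is the biomass term alone, so
downstream relative changes compare growth rates, not penalties.

Uptake capability queries minimize the flux through one exchange with no
biomass requirement; values below −10⁻⁶ (tol_zero, consistent with the
six-decimal rounding used in the screens) count as "can be taken up".

Only objective-level quantities — objective values, growth rates, uptake
minima — are contractually deterministic. Individual fluxes of degenerate
alternate optima are solver-dependent and nothing in the package or its
tests relies on them.

## Community model

Members are merged into one compartmentalized model: every member keeps its
namespaced metabolites and reactions; member exchange reactions become
*shuttle* reactions (member boundary metabolite ↔ shared pool, bounds
±U_free); new community exchanges — the only boundary reactions — carry the
diet bounds. Each member biomass keeps objective coefficient 1. No coupling
constraints tie member fluxes to member biomass, and species composition is
not fixed: it emerges from the optimization, which deliberately represents
the "fully coordinated community" end of the interaction spectrum (the
spatial arena represents the fully individual end). One consequence,
reproduced by the tests, is winner-take-all behavior: with a shared
substrate the more efficient converter receives the whole flux.

Member growth rates are normalized by community growth before effects are
computed, because supplements that raise everyone's growth shift no
composition.

## Screen rules

Growth values are quantized to six decimal places (round half to even, in
decimal arithmetic) before relative changes are formed; the change itself is
computed in decimal so a change of exactly 0.01 compares as exactly 0.01 and
is *rejected* by the strict `> 0.01` rule. A zero baseline with positive
supplemented growth counts as +∞ (de-novo growth, the strongest effect); a
zero baseline with zero supplemented growth counts as 0. In the community
screen, selection requires both the target's effect to exceed the cutoff
*and* strict dominance over every other member's effect — the cutoff alone
would also admit compounds that help a competitor more.

The arena screen rounds the per-replicate relative biomass changes (not raw
biomass, which at gDW scale would vanish at six decimals) and requires
median dominance of the target plus BH-adjusted q ≤ α (default 0.05); a
median-only mode is available for exploratory use. The Wilcoxon rank-sum
test uses the exact null distribution when both samples have ≤ 25
observations without ties, otherwise the normal approximation with tie and
continuity corrections; completely constant data yield p = 1.

## Spatial arena

Defaults: 30×30 grid, 20 founders per species, 12 iterations (13 recorded
time points), dt = 1 h, 15 replicates, medium diluted 1000-fold, supplement
0.01 mM added once at inoculation, cell volume 10⁻⁹ L, founder mass 10⁻¹²
gDW, division at 2×10⁻¹² gDW, movement probability 0.5, diffusion rate 0.1.
The unit bridge is chosen so a 0.01 mM local concentration gives a founder
an uptake bound of 10 mmol·gDW⁻¹·h⁻¹ — a biologically sensible flux scale.

Each step: agents act in seeded random order; per agent the exchange bounds
are tightened to `lb = max(model lb, −amount/(biomass·dt))`, penalized FBA
is solved, biomass is updated linearly (`m ← m(1+μ·dt)`; an exponential
update is available behind a config switch and differs at O((μ·dt)²)),
cell amounts change by `v_ex·biomass·dt`, division places a half-mass
daughter in a uniformly chosen free Moore neighbor (deferred when none is
free), movement goes to a free Moore neighbor with probability 0.5, and a
4-neighbor diffusion sweep with reflecting boundaries closes the step.
Diffusion is on by default because a diffusion-free arena starves agents in
place; rate 0.1 is well inside the ≤ 0.25 stability bound of the discrete
scheme, and the pairwise-flux formulation conserves compound totals to
floating-point precision. An infeasible agent solve (possible only for
unusual models) logs a warning and contributes μ = 0.

Because each grid cell hosts at most one individual and agents exchange
only with their own cell, the per-agent LPs of a step are mutually
independent. They are therefore deduplicated through a cache and solved as
one block-diagonal LP per species and step — numerically identical to
per-agent solves, roughly 30× faster. Supplemented and unsupplemented runs
of replicate r share the derived seed (seed, r), so their difference
isolates the supplement effect.

## Synthetic data

The generator builds toy species as exchange → transporter → catabolism →
biomass chains, giving the closed form `μ = Σ_c availability_c ·
yield(s, c)` that the tests exploit. Study conditions, chosen once:

* diet 10 mmol/L per compound; supplement delta 10 mmol/L;
* default yield 0.002 gDW/mmol — scaled so that 1000-fold-diluted arenas
  stay grid-sparse over 12 iterations instead of saturating the lattice;
* competitor edge 1.2 on shared compounds, making the competitor the more
  efficient generalist (this breaks community-FBA degeneracy the way two
  real strains of unequal efficiency do, and makes neutral supplements
  *counter*-productive for the target in the community screen);
* planted prebiotics at 4:1 target:competitor yield;
* optional private compounds (unique-uptake truth) and co-substrate pairs
  (d consumable only while e is supplied).

What the generator does **not** emulate: genome-scale network topology,
secretion cross-feeding beyond the hand-built producer/consumer fixture,
thermodynamics, regulation, and Biolog measurement noise beyond additive
Gaussian margins. Passing tests therefore demonstrate correctness of the
screening machinery on models whose ground truth is known — not predictive
accuracy on real reconstructions.

## Pipeline

`run_pipeline` executes single-FBA screen → community screen → arena screen
→ intersection → Biolog cross-referencing → class enrichment, writing every
stage table plus a manifest (version, seed, parameters, selections) that
suffices to reproduce every output byte for byte. By default the arena
stage screens only the compounds already selected by both FBA screens: the
final three-way intersection is mathematically unchanged, and the expensive
individual-based stage then scales with the candidate shortlist rather than
the compound universe (`arena_compounds: all` restores exhaustive
screening). Final candidates require all three selections plus a positive
growth confirmation; a lenient mode drops the confirmation requirement when
no phenotypic data exist. The enrichment universe is the target model's
metabolites restricted to class-annotated compounds; unannotated compounds
are dropped with a logged count, and both the two-sided Fisher p and the
one-sided enrichment tail are reported, with BH q across classes.

The host-filtering expectation
`E(p_host_suppl) = p_lawn_suppl · (p_host_base / p_lawn_base)` and a
one-sample chi-squared goodness-of-fit test (df = 1) are provided for
comparing observed host colonization against lawn-driven expectations.

## Problem sizes and verification

The test suite runs entirely on synthetic data: LP optima are cross-checked
against an independently hand-written dense two-phase simplex on 200+ random
networks (≤ 12 reactions) to 10⁻⁷ relative; steady-state residuals are
checked at ≤ 10⁻⁹; arena mass balance at ≤ 10⁻¹² relative per step on a
full-size two-species run; planted-prebiotic recovery uses ten independent
seeds of the two-species, 12-compound collection with full-size arenas
(15 replicates); statistical components are checked against enumeration
(rank combinatorics and hypergeometric tail sums). Unit tests use smaller
arenas (6–12 cell grids, 3–6 steps) where only mechanics, not statistics,
are under test.

## Using real model collections

Nothing restricts the package to toy models: any collection in the JSON
dialect (or SBML subset) with a matching diet table runs through the same
entry points, e.g. gapseq or AGORA-derived reconstructions of a real
two-member community and its growth medium. Such collections are large
external downloads and are deliberately not part of the desk-scale test
suite; with them, the pipeline reports the same quantities the acceptance
script computes for the synthetic collection (screen sizes, overlap
partition, candidate sets).

## Known limitations

* Relative changes ride on six-decimal quantization; growth rates below
  ~10⁻⁴ h⁻¹ lose resolution and should be rescaled.
* Community FBA's coordinated optimum and the arena's individual optima
  bracket, but do not model, intermediate degrees of interaction.
* The arena has no death, lysis, chemotaxis or continuous-time kinetics;
  division halves mass exactly and defers when crowded.
* The pairwise arena screen supports exactly two species; the community
  screen itself handles k ≥ 2.
* Fisher enrichment treats class annotations as flat sets; hierarchical
  ontologies are out of scope.
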