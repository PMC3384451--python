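# Methods

## The crowding-constrained flux balance problem

The solver maximizes an objective flux over the steady-state cone
`S·f = 0` with per-reaction bounds, plus one solvent constraint

    Σ_i c_i |f_i| ≤ V_prot.

The absolute value is implemented by splitting every reversible reaction
into two non-negative directional variables that share the coefficient
`c_i`; a signed sum would let reverse flux subsidize the budget. Both the
primary solve and the optional secondary solve go through scipy's HiGHS
backend.

Because LP flux vectors need not be unique, the default tie-break
(`tie_break="min_crowding_usage"`) re-solves with the objective pinned at
its optimum by an equality row while minimizing total crowding usage. This
makes reported flux vectors reproducible across repeated solves and strips
futile forward/backward cycles on charged reactions. The equality pin is
used instead of an inequality floor because a floor set one tolerance
below the optimum lets the secondary objective shave exactly that
tolerance off the reported growth rate, which breaks limit-equivalence
checks at tight tolerances.

Numerical conventions: feasibility tolerance 1e-9, objective comparisons
1e-6, both HiGHS defaults effectively; infeasible problems return a
status-only solution with no fluxes; an infeasible point inside a glucose
scan is recorded as zero growth and flagged rather than aborting the scan.

### The "unconstrained" sentinel bound

"Unconstrained glucose influx" is realized as an uptake bound at a large
sentinel (`big_bound`, default 1e8 mmol/gDW/h) rather than an infinite
bound, so plain FBA on the same model stays bounded. The sentinel must
exceed `V_prot / min(c)` for every coefficient the sampler can draw;
otherwise the sentinel, not the crowding constraint, becomes the binding
constraint for cheap draws and the optimum becomes a mixture of modes.
With coefficients down to ~1e-7 gDW·h/mmol and `V_prot = 0.2` the largest
charged flux is ~3e6, so 1e8 is safely slack. The growth rates this
produces on the toy network are numerically huge and not meant as
physiology: the toy lumps whole pathways into single reactions, each
drawing one enzyme-scale coefficient, so only ratios (yields, mode
identity, switch fractions) are interpretable.

## Crowding coefficients

`c = (M/V) · v / b` with cell dry-mass density `M/V` (default 340 gDW/l, a
standard bacterial figure; only the product scale matters jointly with
`V_prot`), molar volume `v` from the enzyme's molar mass at 0.73 ml/g of
protein, and catalytic capacity `b = kcat × 3600` (per hour). Units:
`c·f` is a dimensionless volume fraction when `f` is in mmol/gDW/h.

Turnover/mass tables are reduced per enzyme by (1) preferring wild-type
measurements when any exist, (2) keeping the single highest kcat (slow
entries usually reflect poor substrates or non-metabolic activities), and
(3) dropping enzymes whose retained kcat is strictly below 0.01/s — a
boundary value of exactly 0.01/s is kept. Reduction is idempotent.

Enzymes are deliberately **not** identity-mapped to reactions. Each
enzymatic reaction draws one coefficient uniformly (with replacement) from
the pooled empirical distribution; non-enzymatic and exchange reactions
(including the objective drain) carry `c = 0`. Reversible reactions get a
single coefficient for both directions (one enzyme catalyses both). A
draw is a pure function of `(model, distribution, seed)`; per-sample seeds
come from `numpy.random.SeedSequence(master_seed)`, masked to 31 bits.

## The five-reaction switching network

The built-in fixture caricatures glucose metabolism in an
acetate-excreting facultative anaerobe with five lumped internal
reactions around an acetyl-unit branch point:

| reaction      | stoichiometry                                   |
|---------------|-------------------------------------------------|
| R_glycolysis  | glc → 2 accoa + 2 CO2 + 2 ATP + 2 NADH          |
| R_acetate     | accoa → acetate + 1 ATP                         |
| R_waste       | accoa + 2 NADH → waste (lactate/ethanol lumped) |
| R_tca         | accoa → 4 NADH + 1 ATP + 2 CO2                  |
| R_oxphos      | NADH + 0.5 O2 → 2 ATP (P/O = 2)                 |

plus exchanges for glucose, oxygen, acetate, waste and CO2, and an
ATP-drain objective standing in for growth (the toy has no biomass
reaction). All coefficients are keyword-configurable.

Design rationale. The branch point sits at the acetyl unit, and the
acetyl-unit-forming step is lumped formate-lyase style (no NADH of its
own), the way an anaerobically growing acetate producer actually routes
carbon; the acetate branch is then NADH-neutral and the reduced-waste
branch consumes 2 NADH per C2 unit (ethanol-style). This choice gives the
network exactly four elementary modes —

* acetate + waste ("mixed-acid"): 3 ATP/glc,
* waste + TCA: 7/3 ATP/glc,
* acetate + oxphos: 8 ATP/glc,
* TCA + oxphos (full respiration): 24 ATP/glc

— and exactly two (7/3 and 24) once acetate efflux is blocked. An
alternative lumping with the branch point at pyruvate and the
acetyl-forming NADH folded into the acetate branch preserves the yield
ordering but supports only three elementary modes, because the mixed
acetate+waste mode then has no redox closure; it cannot reproduce the
four-mode → two-mode collapse that is the fixture's purpose. Per-reaction
carbon balance (glc 6, acetyl 2, acetate 2, waste 2, CO2 1) and per-mode
redox closure are enforced by tests.

Elementary modes for networks of this size are enumerated by brute force
over internal-reaction support sets: a support is a candidate when the
stoichiometric null space restricted to it is one-dimensional, everywhere
nonzero, sign-feasible for irreversible reactions, and the implied
exchange fluxes respect exchange directionality; support-minimal
candidates are the modes. With one binding crowding constraint and
otherwise unconstrained exchanges the LP optimum lies on the mode
maximizing objective flux per crowding cost, which makes the enumerator an
independent oracle for the LP path (they share no code beyond the model
container).

## Ensemble experiments

Ensembles draw `n` independent coefficient assignments (default study
size 1000) and solve each at unconstrained glucose, recording growth,
glucose uptake, yield (growth per gram glucose, 0.18016 g/mmol), the
low-yield flag (yield strictly below 0.3 g/g — meaningful for
genome-scale models; the toy's drain-based yields sit on an arbitrary
scale), and the excretion class (acetate-only vs lactate/ethanol vs mixed
vs none, efflux tolerance 1e-6).

Yield modes are counted by single-linkage clustering of sorted yields,
splitting where a neighbour gap exceeds `rel_tol = 0.01` of the larger
neighbour and discarding clusters below `min_freq = 0.01` of samples;
the defaults separate the toy's mode yields while absorbing LP noise.

The switch statistic scans the glucose bound and reports
`(max reporter flux − reporter flux at maximal growth) / max reporter flux`
evaluated at the last maximal-growth point (the crowding-limited regime).
The reporter is organism-specific: oxygen uptake for respiring organisms,
formate efflux for a mixed-acid fermenter. Because each draw saturates at
a glucose uptake set by its own coefficient scale, meaningful scans use a
per-draw grid (e.g. up to 1.5× that draw's unconstrained uptake); a single
shared grid spanning orders of magnitude would sit entirely in the crowded
regime for most draws and report no switch.

Knockouts set an exchange's efflux upper bound to zero (idempotent,
non-mutating). Overexpression appends a reaction with a forced lower
bound; built-in specs are a water-forming NADH oxidase (NOX,
NADH + 0.5 O2 →) and an alternative oxidase (AOX) with the same net redox
chemistry at zero ATP — at this level of lumping the two differ only in
label, since neither conserves energy.

## Fitting the crowding budget

`fit_vprot` grid-searches `V_prot`, running an ensemble per grid value and
minimizing

    ((μ_fit − μ_obs)/μ_obs)² + ((G_fit − G_obs)/G_obs)²

with `μ_fit`, `G_fit` the ensemble means of maximal growth and glucose
uptake (the aggregation across samples is a package choice; mean is used).
The same master seed is used at every grid value (common random numbers),
so the criterion profile over the grid is noise-free in `V_prot`; ties go
to the smallest grid value.

Recovery protocol. Synthetic observations are generated by running the
same ensemble at a known `V_prot`. With a degenerate (single-coefficient)
distribution the observations are deterministic and recovery is exact for
any seeds. With a broad distribution, recovery tests also share the master
seed between generation and fitting, making the observations noiseless
targets. This is deliberate: `V_prot` enters the model only through
`V_prot × (sampled best mode ratio)`, so with independent draws of an
orders-of-magnitude-wide coefficient distribution, the sampling error of
any location estimate of the ratio across 100 draws is far larger than a
0.01 grid step — measured recovery errors were 0.01–0.05 for both 8-decade
and 2-decade distributions. Scale and budget are jointly unidentifiable
from finite independent samples; matched draws isolate what the fit can
actually test, namely that the criterion's minimum sits at the generating
budget.

## Synthetic data: what it does and does not emulate

The turnover/mass generator draws kcat log-uniformly over 0.01–1e4 /s and
masses over 1e4–1e6 g/mol (defaults), yielding crowding coefficients
spanning ~8 decades — the qualitative shape of curated database extracts
(broad, multi-decade, no obvious parametric family; log-uniform is the
least-informative match and both ranges are configurable). A configurable
fraction of enzymes receives an extra mutant record and another fraction
falls below the 0.01/s floor, so the reduction rules are exercised. It
does not emulate correlations between kcat and mass, substrate
multiplicity, or organism-specific coverage.

The branched-network generator produces a glycolysis-like backbone
(2 ATP, optionally 2 NADH per glucose) feeding `k ≥ 2` alternative
branches with prescribed whole-pathway ATP yields; with cofactor coupling
each branch reoxidizes its share of backbone NADH, giving exactly one
redox-closed elementary mode per branch. It does not emulate genome-scale
topology (shared cofactor pools across many reactions, parallel isozymes,
biomass drains), so toy-passing tests demonstrate correctness of the
optimization and ensemble machinery, not genome-scale predictive accuracy.

## Known limitations

* Genome-scale claims (organism-specific low-yield fractions, repression
  fractions, fitted budgets near 0.15–0.2) require the published models
  and curated coefficient tables as external inputs; nothing here bundles
  them.
* Brute-force mode enumeration is exponential in internal reactions
  (capped at 16) — by design, since it serves as an oracle, not a tool.
* The ensemble philosophy treats coefficients as exchangeable across
  reactions; organisms with strongly structured enzyme costs would need
  per-reaction assignments, which the containers support but the sampler
  does not produce.
* Michaelis–Menten saturation is not modelled; catalytic capacity is
  taken at `b = Vmax`.
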