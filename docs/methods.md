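# Methods

`deadwoodnet` couples strategic conservation planning (where to create
forest reserves) with operational planning (where to place 1-ha deadwood
islands and how to manage every other stand) in a managed temperate
forest landscape, for a deadwood-dependent umbrella species such as the
stag beetle *Lucanus cervus*. This note documents the models, the
synthetic data they run on, the numerical choices, and what the tests do
and do not demonstrate.

## Deterministic model

Every stand is either set aside as a reserve (`y_i = 1`) or managed
under exactly one of `M` regimes (`x_ij = 1`). The objective maximizes
total net present value minus a pro-rata correction for deadwood islands
placed on managed stands:

```
max  Σ_ij  npv_ij x_ij  −  (npv_ij / area_i) auxz_ij ,
```

where `z_i` counts the islands in stand `i`, and `auxz_ij = z_i · x_ij`
is linearized with three big-M rows using `BPT`, the largest per-stand
candidate-point count. Islands on reserves are free — the reserve's NPV
is already foregone in full.

Constraint families:

* **Partition.** `Σ_j x_ij + y_i = 1`; existing reserves are fixed
  `y_i = 1` and carry no regimes.
* **Even wood flow.** Per decade, harvested volume lies within ±30% of a
  free bound `VolB` (its optimized value is a study outcome; the robust
  model adds a floor, pro rata to the 200,000 m³/decade of the full-size
  study area).
* **Sustained stock.** Final standing volume ≥ initial standing volume.
* **Reserve share.** Reserve area ≥ 10% of the forest.
* **Minimum reserve blocks (ring inequalities).** Every maximal
  connected block of reserves must reach 50 ha: any undersized selected
  block must recruit a neighbouring stand. These exponentially many
  inequalities are separated lazily: solve, enumerate maximal reserve
  blocks on the stand-neighbourhood graph, add one cut per undersized
  block, re-solve until clean. Cuts are valid for any objective, so a
  robust solve is warm-started with the deterministic solve's cuts.
* **Island network.** Candidate island centres form a grid clipped to
  the stands; two centres are adjacent when their distance is at most
  the dispersal distance plus two island radii (56.4 m each for 1 ha),
  giving thresholds 162.8/212.8/312.8/412.8 m for 50/100/200/300 m
  dispersal. Selected centres must form a single connected network
  containing a root point (in the largest existing reserve), enforced by
  single-commodity flow: the root injects `sumPT − 1` units, every other
  selected point consumes one, and flow is confined to selected arcs via
  the product linearization `linSum_ij = sumPT · k_ij`. Each reserve
  must contain at least one island (`z_i ≥ y_i`), which is what forces
  reserves to be stitched together by stepping stones.

Reserve candidacy is restricted to beech- or silver-fir-dominated stands
older than 160 years (strict), plus all existing reserves.

Solved with HiGHS (branch-and-cut through `scipy.optimize.milp`) at a 3%
relative gap (5% for the robust model). Every returned plan is re-audited
arithmetically outside the solver: partition, flow band, stock, reserve
share, block minima, `z ≥ y`, exact `auxz = z·x` and
`linSum = sumPT·k` identities, rooted connectivity, root injection and
unit consumption. Strict inequalities of the formulation are implemented
non-strictly, as MILP requires.

## Economics

Regime NPV treats the initial standing stock as the investment:

```
NPV = −IniStock + Σ_{i=1..T} ThinNet_i (1+r)^−(i−1) + FinStock (1+r)^−(T−1)
```

with a 50-year horizon in five 10-year periods; each period's net
revenue is booked in the period's final year (a deliberately
conservative convention — booking mid-period would raise all NPVs
slightly but change no comparison). The deterministic discount rate is
1%.

Retention corrections subtract the value of habitat trees (2.5/ha on
spruce-dominated stands — fewer because of bark-beetle risk — 5/ha
otherwise; a tree is priced as a configurable mean crop-tree volume,
default 3 m³, times the stand's implied net price) and the cost of
topping up natural deadwood input to 0.9 m³/ha/yr (the input that
sustains a 35 m³/ha deadwood stock) with thinned volume; natural input
above the requirement is credited as thinning revenue at a reduced
price factor (default 0.5). The deadwood terms are applied undiscounted;
both terms commute.

## Uncertainty engine

Three independent sources perturb the NPVs, combined in 100 Monte-Carlo
scenarios per climate trajectory (400 pooled):

* **Prices.** Driftless geometric Brownian motion per species; yearly
  log-return volatility is estimated from a 17-year price history, with
  substitution from the neighbouring (next larger) assortment class when
  a series exceeds a volatility cap (default 0.20/yr) — small
  assortments are too volatile to extrapolate over 50 years. Scenario
  revenues are scaled by the path value at each period's end.
* **Discount rates.** Risk-free 0.67% plus an Exp(3.5) deviate,
  truncated at its 99.9% quantile and rescaled onto [0.0067, 0.03]:
  rates span the interval with monotonically decreasing density.
* **Storms.** Yearly maximum wind speeds follow a Gumbel distribution
  fitted by maximum likelihood to a 48-year record; a storm happens in
  any simulation year with the annual occurrence probability of the
  41.67 m/s reference speed (storm "Lothar"). A storm damages each
  stand by the logistic damage probability of its mean tree
  (`g = β1 + α ln DBH + γ ln h +` topex-class effect `+ f(N,E)`), used
  directly as the damaged area share; the damaged share reduces
  harvested and standing volumes in the period of occurrence and all
  later periods, the damaged volume enters the deadwood pool (not
  salvage revenue), and prices drop 25% in the storm period. The spatial
  smoothing `f(N,E)` is a radially decaying term in distance to a
  configured storm centre; its coefficients — like the per-species
  damage coefficients — are synthetic defaults chosen to give mature
  stands mean-tree damage probabilities of roughly 0.1–0.5, since the
  original model's fitted values are not published.

Climate trajectories (RCP2.6/4.5/6.0/8.5) act as multiplicative growth
modifiers on the synthetic regime outcomes, deliberately non-monotone in
forcing (0.92, 1.00, 1.10, 1.04): the low-forcing pathway is the least
productive, the moderate one the most. Expected NPVs weight the four
trajectories equally.

## Robust counterpart

The robust model maximizes `E[NPV] − t` where `t` bounds, with
confidence `1 − ε` (ε = 0.05), how far total NPV can fall below its
expectation — i.e. it protects the 5% Value-at-Risk. Per regime `j`, the
covariance of stand NPVs across the 400 scenarios is repaired to the
nearest positive-definite matrix (eigenvalue clipping at a relative
floor of 1e-12; the Cholesky factor reproduces the repaired matrix to
1e-8 relative) — regimes are treated as mutually independent. The
Bernstein-type certificate is

```
−t + β Σ_ji ln cosh(a_ji/β) − β Σ_ji ln cosh(b_ji/β) + β ln(1/ε) ≤ 0,
a_j = L_jᵀ x_j ,   b_j = L_jᵀ (auxz_j / area) .
```

The subtraction of the island-correction sum follows the source
formulation as printed; a config flag (`second_term_sign`) switches to
the additive (strictly conservative) reading, since a safe approximation
normally accumulates uncertain terms. In 1-D the certificate reduces to
`t = β ln cosh(c/β) + β ln 20`, which the tests check against a numeric
oracle.

**Linearizing ln cosh.** Both sums pass through piecewise-linear handles
of `ln cosh` built to keep the certificate conservative in both
directions:

* the *added* sum uses the epigraph of the chord interpolant (24 chords
  on [−10, 10] plus slope-±1 asymptotic pieces, since
  `ln cosh x → |x| − ln 2`) — plain linear rows; the solver settles on
  the interpolant, which over-approximates `ln cosh`;
* the *subtracted* sum must not be over-estimated, so it uses a
  segment-selection (λ/binary) formulation whose node values are shifted
  down by the local chord error: the representable values always lie at
  or below `ln cosh`. Per-block domains are clipped to what the `auxz`
  bounds allow, and blocks with vanishing domains are fixed to zero.

This keeps the guarantee valid without the cost of a full SOS2
treatment of the convex side; refining the segment counts tightens `t`
monotonically up to the stated chord-error bound. The hypograph side
defaults to few (2–6) segments: conservatism, not accuracy, is the
binding requirement, and the binaries dominate solve time.

**β calibration.** With decisions fixed at the deterministic optimum,
`t(β)` (exact `ln cosh` form) is minimized by bounded search over
`log β`, with a floor of 1e-4 × mean |E npv| against division blow-ups;
the minimizer is the proxy. A multiplicative grid around the proxy
(default ×{0.25, 0.5, 1, 2, 4}) is solved and ranked by Monte-Carlo VaR
on the scenario set; the best is kept. On small instances the minimum
often sits in the ℓ1 regime of the bound (β at the floor), where
`t → Σ|a| − Σ|b|` — the worst-case-sum reading of the certificate.

## Evaluation

A plan's per-scenario total is
`Σ npv_ijs (1 − z_i/area_i)` over its managed stands; reserves
contribute zero. VaR is the empirical lower 5% quantile with the type-1
(lower-interpolation) convention, fixed because the certificate bounds a
quantile and interpolation conventions differ. Deterministic and robust
plans are compared on the same pooled 400-scenario set, with paired
bootstrap CIs (1,000 resamples). The no-network baseline for NPV-loss
percentages is the same instance solved without the reserve/island
constraint families.

## Synthetic data: what it emulates, what it does not

The generators stand in for a single-tree growth simulator, GIS stand
maps, state price lists and weather records:

* **Landscape.** A perturbed Voronoi tessellation of a square; total and
  existing-reserve areas hit their configured targets (1% tolerance at
  the default scales) by subset-sum selection of whole stands. Old
  (>160 yr) beech/fir stands — the reserve candidates — are grown as one
  contiguous massif on the adjacency graph, mirroring the clustering of
  old growth on less accessible terrain; without this, isolated
  candidates make 50-ha reserve blocks unattainable. Existing reserves
  are drawn from inside the massif.
* **Regimes.** Stand volume grows by an additive, site- and
  climate-scaled increment per decade; regime `j` removes a fraction of
  post-growth volume. Regime 1 never harvests; "Liocourt" and "Meyer"
  selection systems harvest flat moderate fractions; the remaining
  regimes form an intensity gradient with front-loaded removals.
  Additive growth gives a mass balance that makes cumulative removals
  monotone in intensity rank — a property the tests assert.
* **Prices/winds.** Driftless log-walks with per-assortment volatility;
  Gumbel yearly wind maxima with known (μ, s) so estimator recovery is
  testable.

Not emulated: tree-level structure and mortality, species mixture within
stands, climate-dependent storm frequency, bark-beetle and snow
disturbance, assortment-level bucking, price co-movement across species.
Passing tests therefore demonstrate correctness of the optimization and
simulation machinery and the qualitative study findings (network costs a
few percent of NPV; uncertainty shrinks profitability; robust plans
diversify regimes and dominate deterministic plans on VaR), not
quantitative transferability to any real forest.

## Problem sizes and defaults

The default deterministic instance is 400 ha / 40 stands (existing
reserves 22.9 ha — the same share as the full 2,534/145 ha area), eight
regimes, four trajectories, a 150 m candidate grid (169 points, ~1,200
arcs at 100 m dispersal) and the study-level 10% reserve share, 50 ha
block minimum and ±30% flow band. Replicated robust-vs-deterministic
experiments use a 200 ha / 22-stand, four-regime variant (20 ha block
minimum, 15% reserve-area matching tolerance — whole 9-ha stands cannot
hit a 11.4 ha target to the percent) sized so ten full studies run in
minutes. The full-scale landscape (2,534 ha, 120 stands, up to 50
regimes) is a generation preset; its MILP is beyond what an open-source
solver settles at these gaps in reasonable time, and no reported result
depends on it.

## Known limitations

* `VolB` has no objective term in the deterministic model, so the
  realized maximum band deviation is typically exactly 30% — any value
  in the feasible interval is optimal.
* Scenario NPVs apply the retention correction as a static (per
  trajectory) shift; storm-added deadwood does not reduce the
  supplementation cost inside scenarios.
* Period-end revenue booking plus 50-year discounting makes expected
  NPVs under uncertainty fall well below deterministic NPVs; the drop is
  steeper than in landscapes with mid-rotation cash flows.
* The oracle-equivalence guarantee is exhaustive only at toy scale
  (≤6 stands, ≤3 regimes, ≤9 points); larger instances rely on the
  solver's gap proof plus the independent constraint audit.
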