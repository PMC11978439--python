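# Methods

`antnets` simulates the transportation networks of polydomous wood-ant
(*Formica lugubris*) colonies at the nest level and measures how those
networks restructure when a foraging resource is removed. This note
documents the model, its parameters, the synthetic study design, and the
numerical and design choices behind the implementation.

## The model

A colony network is a planar spatial graph in a 60 × 60 m arena. Nodes are
**nests** (with a size, the number of resident ants) and **trees**
(honeydew-bearing food sources, all of equal quality). Edges are straight
**trails**: *foraging* trails join a nest to a tree, *internest* trails join
two nests. A trail's **strength** is the density of ants using it (ants/mm).
Trails never cross — when a candidate trail would intersect an existing one
it simply cannot form — which keeps every network planar by construction.

### Initialization

1. **Trees**: `round(0.01 trees/m² × 3600 m²) = 36` trees are scattered by
   rejection sampling with a 2 m inhibition distance.
2. **Nests**: the nest count is drawn from a negative binomial truncated to
   the observed range [4, 20]. The first nest lands uniformly in the arena;
   each later nest is offset from a uniformly chosen earlier nest by a
   gamma-distributed distance (draws under 1.5 m redrawn from U(1.5, 2) m)
   at a uniform angle, redrawn until inside the arena. Sizes are gamma
   draws capped at the distribution's 95th percentile.
3. **Trails**: every nest first links to its nearest reachable nest (ties
   to the lowest node id). Each nest then draws a Poisson number of
   foraging trails; nests claim their trails in ascending order of size,
   each to the closest tree reachable without crossing existing trails. A
   nest that cannot reach enough trees gets fewer trails.
4. A gravity strength update (below) initialises all trail strengths, and
   the clock is set to −8 weeks (the burn-in).

### Weekly update

Each timestep is one week of the active season and applies, in order:

1. **Growth.** Each foraging trail delivers its strength to its nest. Each
   internest trail carries its full strength from the endpoint with the
   higher *per-capita* foraging inflow to the poorer endpoint (well-supplied
   nests subsidise dependants; exact ties carry nothing). With net income
   *f* the nest size updates logistically,
   `s ← s + κ·f·s·(1 − s/K)` for `f ≥ 0`, and `s ← s + κ·f·s` for `f < 0`
   (shrinkage is not capacity-limited).
2. **Nest abandonment.** Nests below the size threshold (the 5th percentile
   of the nest-size distribution) are abandoned with all their trails, in a
   single pass (no within-step cascades).
3. **Budding.** Each nest buds with probability `min(1, c_bud·s)`. The
   daughter takes a fixed fraction (default 10%) of the parent's workers,
   is placed by the initialization offset rule, and connects to the parent
   by an internest trail (placement redrawn when that trail would cross an
   existing one). Budding from a small parent therefore produces a daughter
   near the abandonment threshold that must establish a positive income
   quickly or fail — this reproduces the observed churn of new nests
   emerging and declining. An alternative in which daughters draw a full
   initial size from the founding distribution was rejected: under the
   income rule above such nests can never fail (a nest without foraging
   trails has non-negative income), so nest counts grow without bound and
   no fluctuation occurs.
4. **Trail formation.** Each nest, independently for each trail kind, adds
   with a small probability `p_new` one trail to a target drawn uniformly
   among feasible candidates (active, not yet connected, reachable without
   crossing; excluded trees are never candidates).
5. **Strength update.** Gravity formulae, fitted separately by kind:
   internest `θ_i (s_a s_b)^{α_i} / ℓ^{β_i}`, foraging
   `θ_f s_n^{α_f} / ℓ^{β_f}` (trees carry no mass term).
6. **Trail abandonment.** Trails below the strength threshold are removed.

Stochasticity enters only through initialization, budding and trail
formation; everything else is deterministic given the state.

## Parameters

Printed field-system constants: arena 60 m, tree density 0.01/m², tree
inhibition 2 m, nest range [4, 20], minimum offset 1.5 m with U(1.5, 2)
redraw, 28-week seasons, 8-week burn-in. All remaining constants are
package defaults, chosen once so that simulated colonies are realistic for
this system — roughly 10–11 nests of order 10⁴ ants, six actively used
trees, trail strengths of order 1 ant/mm, a total trail length near 125 m,
global efficiency near 0.1 m⁻¹ and single-trail robustness near 0.93 at the
start of the experiment, with slow nest turnover and gradual fragmentation
over three seasons:

| parameter | default | unit / meaning |
|---|---|---|
| `nest_count_n`, `nest_count_p` | 8, 0.4 | negative binomial (mean 12, truncated to [4, 20]) |
| `nest_distance_shape/scale` | 2.2, 2.7 | gamma placement offsets, mean ≈ 5.9 m |
| `nest_size_shape/scale` | 2, 5000 | gamma nest sizes, mean 10⁴ ants |
| `nest_size_cap` | 23 719 | 95th percentile of the size gamma |
| `nest_abandon_threshold` | 1 777 | 5th percentile of the size gamma |
| `foraging_count_mean` | 1.5 | Poisson initial foraging trails per nest |
| `growth_rate_scale` κ | 0.1 | growth per unit income per week |
| `carrying_capacity` K | 30 000 | ants per nest |
| `budding_coefficient` c_bud | 3×10⁻⁷ | per ant per week |
| `bud_size_fraction` | 0.1 | share of parent workers in a bud |
| `new_trail_prob` | 0.005 | per nest per kind per week |
| `trail_abandon_threshold` | 0.25 | ants/mm |
| `gravity_internest` (θ, α, β) | (3×10⁻⁴, 0.5, 1) | strength = θ(s_a s_b)^α/ℓ^β |
| `gravity_foraging` (θ, α, β) | (0.06, 0.5, 1) | strength = θ s^α/ℓ^β |

All parameters live in `ModelParams` and can be overridden from a YAML
config, so re-estimated values (e.g. from the `estimation` module applied
to colony-mapping data) drop in without code changes.

## The experiment

A paired seven-arm design on each network. After the burn-in the t = 0
state is copied into four branches: control, and exclusion of the tree with
the **strongest** cumulative foraging trail strength, of a **random** used
tree, and of the **weakest**. The random tree is drawn from the used-tree
pool (trees with at least one foraging trail), so every exclusion arm
removes exactly one actively used resource. Excluded trees lose their
foraging trails and cannot receive new ones. At t = 28 each exclusion
branch forks into *sustained* (press perturbation) and *reintroduced*
(pulse: the tree becomes available again but its trails must re-form
spontaneously). All seven arms run to t = 84 with every measure recorded at
every timestep.

Randomness is hierarchically seeded from (master seed, network index, phase,
branch), so arms share their pre-fork history bit for bit, diverge
stochastically afterwards, control trajectories are independent of the
other arms' choices, and ensembles are reproducible for any worker count.
Networks whose burn-in endpoint uses no tree are regenerated from the next
derived seed (logged), keeping ensembles full.

## Measures

* **Global efficiency** — mean of inverse shortest-path distances (summed
  trail lengths) over unordered node pairs; disconnected pairs contribute
  zero; not normalized by an ideal graph, so the unit is 1/m.
* **Robustness** — mean over single-trail deletions of E(G−e)/E(G), the
  efficiency retained after losing one trail (≈ 0.9 for typical colonies).
  The complementary loss convention `1 − E(G−e)/E(G)` is available via
  `robustness_as_loss`.
* **Cost** — total trail length (m); **normalized cost** divides by colony
  population (missing when the population is zero).
* Counts and ratios: nests, *used* trees (≥ 1 foraging trail), trails by
  kind, per-nest ratios, components of the measured node set, population.

The measured node set is active nests plus used trees: an unused tree is
part of the environment, not of the transportation network, and would
otherwise dilute efficiency. All of the above are also computed for the
internest subnetwork (trees and foraging trails excluded).

Ensemble statistics are means with normal-approximation 95% CIs, and
treatment effects are **paired** relative differences — each treatment
instance compared to the control instance of the same network, then
averaged (the mean of per-pair ratios, not the ratio of means).

## Numerical choices

* Segment crossing uses exact-sign orientation tests in double precision.
  Sharing an endpoint is not a crossing (trails legally meet at nodes);
  collinear overlap of positive length is (no stacked trails); an endpoint
  lying on another trail's interior is tolerated (nodes are zero-radius
  points, and the event has measure zero under continuous placement).
* Shortest paths use a vectorised Floyd–Warshall on dense matrices; the
  measured graphs have a few dozen nodes, where this outperforms sparse
  solvers by a wide margin and is exact.
* Rejection sampling (tree placement, nest offsets, truncated counts) uses
  explicit retry budgets and raises instead of hanging on infeasible
  configurations.
* Gravity fitting is ordinary least squares on the log scale; the truncated
  negative binomial is fitted by truncated-likelihood MLE (Nelder–Mead on
  (n, logit p)); gamma fits fix the location at zero.
* Ties in focal-tree selection and nearest-neighbour searches break to the
  lowest node id, keeping every run reproducible.

## What the synthetic data do and do not show

The synthetic mapping-data generator (`estimation.synth_mapping_data`)
emulates the fields a colony-mapping survey records — nests with positions
and size estimates, trails with lengths and strengths — by generating
colonies from the model itself and adding multiplicative lognormal noise to
trail strengths. It exercises the full estimate→configure→simulate round
trip, but because the data are drawn from the model's own families, passing
recovery tests shows correctness of the fitting machinery, not that the
default parameters equal those of any real ant population. Real mapping
tables in the same CSV schema can be substituted directly.

Problem sizes in the test and acceptance runs (hundreds to a few hundred
networks rather than many thousands) are the package's default study scale;
ensemble means are stable at this scale, while confidence intervals are
correspondingly wider than at larger ensemble sizes.

## Known limitations

* Tree quality is uniform; there is no mechanism drawing colonies back to a
  reintroduced resource beyond ordinary stochastic trail formation.
* No terrain, obstacles, curved trails, or within-season environmental
  variation; no individual-ant behaviour or pheromone dynamics.
* Nests with neither foraging nor internest income hold their size
  indefinitely; colony decline operates only through the flow-imbalance and
  threshold mechanisms described above.
* Simulated colonies fragment somewhat faster than mapped colonies
  typically do, and the cost trajectory drifts upward late in long runs as
  stochastic trail formation outpaces abandonment.
* Under the default parameters the *immediate* exclusion response is
  sharply structured (efficiency rises for weak/random targets and falls
  for strong ones; robustness losses scale with target importance), and the
  robustness deficit persists through all three seasons, but the efficiency
  deficit of strongly perturbed networks fades over the following seasons
  rather than deepening; the long-horizon efficiency response is sensitive
  to the trail formation/abandonment balance.
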