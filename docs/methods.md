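# Methods

## The model

`germsoma` models the evolutionary origin of germ–soma division of labor in
simple multicellular colonies (the motivating system is volvocine green
algae). A finite population of asexual haploid cells forms undifferentiated
colonies: each founder cell goes through `n` binary divisions, producing a
colony of `S = 2**n` cells. Colonies surviving density-dependent viability
selection disintegrate, and every released cell independently founds a
daughter colony with probability equal to its own fertility.

### Cell fitness and trade-offs

Each cell carries two major genes with allelic effects `x` (fertility) and
`y` (viability), both in [0, 1]. Developing and maintaining one function
detracts from the other, so the components follow a multiplicative
trade-off model:

    f = x^alpha * (1 - y)^beta
    v = y^alpha * (1 - x)^beta

`alpha > 0` shapes the direct effect, `beta >= 0` the strength of the
trade-off (absent at `beta = 0`). Direct effects are assumed at least as
strong as indirect ones, so `beta > alpha` triggers a validation warning
rather than an error.

### Developmental plasticity

Before any genetic specialization, an environmental dichotomy (cell size,
inner/outer position, a chemical gradient) labels a fraction `p` of each
colony's cells *proto-germ* and the rest *proto-soma*. Two conditionally
expressed regulatory genes implement plasticity: in proto-germ cells the
germ suppressor `g` reduces the expressed viability-gene effect from `y` to
`(1-g)y`; in proto-soma cells the soma suppressor `s` reduces the expressed
fertility-gene effect from `x` to `(1-s)x`. The suppressed effect is
substituted throughout the component formulas, so suppression both
abolishes the suppressed function and *relieves the trade-off* on the
enhanced one — that relief is the selective advantage of differentiation.
Plasticity is costly: proto-germ fertility and proto-soma viability are
multiplied by the Gaussian factor `exp(-(effect/c)^2)`; `c` (`cost_scale`)
is larger for cheaper plasticity, the factor is 1 at zero suppression and
has zero slope there, so costs do not oppose the *first* appearance of
regulation.

Role-specific components:

| role       | fertility                                  | viability                                |
|------------|--------------------------------------------|------------------------------------------|
| proto-germ | `x^a (1-(1-g)y)^b * exp(-(g/c)^2)`         | `((1-g)y)^a (1-x)^b`                     |
| proto-soma | `((1-s)x)^a (1-y)^b`                       | `y^a (1-(1-s)x)^b * exp(-(s/c)^2)`       |

At the fully differentiated corner (`x = y = g = s = 1`) germ cells have
maximal fertility but zero viability and soma cells the reverse.

### Demography

Colony viability `V` is the average of its cells' viabilities. A colony
survives to reproduction with the Beverton-Holt probability

    P(V, N) = 1 / (1 + (b - 1) N / (K0 V)),

with `N` the colony count, `K0` the maximum carrying capacity and `b` the
offspring-number parameter. The fitness of a founder cell and the induced
carrying capacity of a monomorphic population are

    w(f, v, N) = S f P(v, N)          (w = 1 at N = K)
    K(f, v)    = K0 v (S f - 1)/(b - 1),

with extinction for `S f <= 1` and `K ~ K0 S f v/(b-1)` for large colonies.
The deterministic recursion `N' = w N` approaches `K` monotonically.

### Mutation

Mutation occurs during colony growth: at every division each daughter cell
mutates each of the four genes independently with probability `mu`
(continuum of alleles). A mutation perturbs the allelic effect by a
zero-mean Gaussian step of s.d. `sigma_m`, redrawn (rejection sampling)
until the result lies in [0, 1] — no probability mass piles up at the
boundaries. The expected number of cells per colony carrying a mutation at
a given gene is `S (1 - (1-mu)^n)`, approximately `mu S log2 S`.

## Adaptive-dynamics analysis

With ecology fast relative to evolution, a rare mutant founder in a
resident population at its carrying capacity has invasion fitness

    lambda(m; r) = S F_m / (1 + (V_r/V_m)(S F_r - 1)),

where `(F, V) = (p f_g + (1-p) f_s, p v_g + (1-p) v_s)` are the
monomorphic-colony components. `lambda ≈ (F_m V_m)/(F_r V_r)` when
`S F_r >> 1`. The selection gradient decomposes as

    d ln(lambda)/dz = d ln F/dz + q d ln V/dz,   q = 1 - 1/(S F_r).

The weight `q < 1` is the analytic residue of the individual-versus-colony
conflict: fertility is an individual-level trait while viability acts
through colony survival, whose density-dependent component saturates at low
crowding. Consequences, all verified against finite differences of the
invasion fitness in the tests:

- **Major loci (no regulation).** `D_x = alpha/x - q beta/(1-x)`,
  `D_y = q alpha/y - beta/(1-y)`. At the joint singular point
  `x_hat = alpha/(alpha + q beta) > alpha/(alpha+beta) >
  y_hat = q alpha/(q alpha + beta)`: the fertility gene overshoots and the
  viability gene undershoots the common large-colony limit, with smaller
  colonies amplifying the conflict (lower equilibrium viability, smaller
  populations). Eliminating `q` gives the equilibrium relation
  `alpha^2 (1-x)(1-y) = beta^2 x y`. The solver works in the single
  unknown `q` (bracketed root of the self-consistency `q = 1 - 1/(S f)`),
  reports boundary equilibria (`beta = 0` fixes both effects at 1)
  explicitly, and exposes `large_S=True` for the symmetric limit where
  `x_hat = y_hat` exactly.
- **No-regulation stability.** At the major-locus optimum the state
  `g = s = 0` is singular (the first-order benefit of suppression — the
  relieved trade-off — exactly cancels the first-order loss of the
  suppressed function; the Gaussian cost contributes nothing to first
  order). Its stability is that of the symmetric Jacobian of the
  linearized `(g, s)` gradients; for `p = 1/2` the state is unstable iff

      alpha^2 (2 - 1/beta) - alpha > 2 / c^2.

  Strong trade-offs, strong direct effects and cheap plasticity launch
  differentiation; the no-cost boundary (`c -> inf`) is
  `beta = alpha/(2 alpha - 1)`, which requires `alpha > 1` to be
  attainable within `beta <= alpha`. The closed form is cross-checked by a
  finite-difference Jacobian of the numeric gradient map at `S = 2^24`.
- **Differentiated singular point.** For strong trade-offs the major
  effects fix at `x = y = 1` and the suppressors equilibrate at
  `g = s = c sqrt(beta/2)` (the maximum of `z^beta exp(-(z/c)^2)`): partial
  suppression when plasticity is costly (`c < sqrt(2/beta)`), complete
  suppression (`g = s = 1`) when it is cheap. This sits on the trait-space
  boundary, so the suppressor gradients vanish there while the major-locus
  gradients point outward; both facts are asserted numerically.

## Numerical protocol and desk scale

Runs start from a monomorphic population: major effects drawn uniformly,
suppressors at zero, colony count at the founder's predicted carrying
capacity. Because a uniform draw can be demographically hopeless (S f <= 1),
the founder is redrawn (up to 200 times, same seeded generator) until its
carrying capacity reaches 150 colonies, falling back to the best draw for
deliberately small configurations; without this the desk-scale runs begin
with a handful of colonies and die of demographic noise in the first
generations.

`K0` is calibrated so the *undifferentiated* population holds a target
number of colonies — 300 at desk scale (the cluster-scale experiments this
package reduces hold a few thousand). Calibration is analytic by default
(place the major loci at their singular point and invert `K(F, V)`, which
is linear in `K0`); a literal pre-run calibration with regulation frozen is
also provided and tested against it.

Defaults (`ModelParams()`): `alpha = 2`, `beta = 1`, `cost_scale = 2`,
`p = 1/2`, `n_divisions = 4` (S = 16), `mu = 1e-4`, `sigma_m = 0.05`,
`b = 2`. The sweep grid spans `beta ∈ {0.25, 0.5, 1}`,
`cost_scale ∈ {0.5, 1, 2}`, `mu ∈ {1e-4, 3e-4, 1e-3}`, crossing the phase
boundary: the (1, 2, 1e-3) corner differentiates completely, the
(0.25, 0.5, 1e-4) corner never leaves `g = s ≈ 0`. Outcomes are classified
from the means over the final 10 % of records: `complete` if x, y, g, s all
exceed 0.9; `no_plasticity` if g and s stay below 0.1; `partial` otherwise;
thresholds are configurable. Sweep replicates draw their seeds from a
spawned `SeedSequence`, so record sets are reproducible regardless of
execution order; the driver may stop a run early once the complete-outcome
condition is already met on the running tail (this can only shorten runs
that have differentiated, not change a classification).

## What a green test does and does not establish

The synthetic world *is* the model: there is no external data, and every
test compares the stochastic implementation with the package's own
analytic layer or with independent oracles (finite differences, tree
enumeration, scipy's truncated normal, brute-force means). Green tests
therefore establish internal consistency of simulation and theory at desk
scale, and the qualitative phase structure (which corners differentiate).
They do not establish anything about real volvocine biology, nor about
cluster-scale quantitative details: at 300 colonies drift is far stronger
than at a few thousand, stochastic extinction of marginal populations is
possible (it is reported as a truncated trajectory, never silently
retried), and the stationary colony count sits slightly below the
deterministic carrying capacity (a `O(1/K)` curvature effect of the
Beverton-Holt nonlinearity — visible at toy populations, negligible at the
population sizes the demographic-fidelity test uses).

## Numerical choices

- Finite differences: central, step `1e-6` in traits (the invasion fitness
  is 1 at the resident, so absolute and log derivatives coincide);
  stability Jacobians use step `1e-4` around the singular point.
- Root finding: `brentq` on `q ∈ (1e-12, 1]` with `xtol = 1e-15`
  (major equilibrium) and on the stability margin over `beta` (phase
  boundary); boundary-curve points with no sign change in range are
  omitted with a warning.
- Fitness components are defensively clipped to [0, 1] with a logged
  warning if clipping ever exceeds 1e-12 (it does not for valid inputs).
- The colony count is hard-capped at ten times the theoretical maximum
  carrying capacity `K0 (S-1)/(b-1)`; exceeding it raises an error, as it
  can only indicate a transcription defect in the demographic algebra.
- Roles are re-drawn uniformly at random every generation (exactly
  `round(p S)` proto-germ cells per colony): fitness aggregates depend only
  on counts, and a random draw avoids introducing artificial heritability
  of the environmental cue.
- The trajectory recorder stores means only; per-cell state is available
  as an optional terminal snapshot (the fertility/viability scatter of the
  two roles).

## Known limitations

- Cells are exchangeable within a colony: no spatial structure, no
  asymmetric division, no within-colony cell death, exactly two roles.
- The analytic minor-locus layer (stability condition, singular
  suppressor value) is a large-colony approximation; at `S = 16` the
  finite-`q` corrections shift the phase boundary slightly. The
  finite-difference route covers any finite `S`.
- The monomorphic decomposition uses the exact fraction `p`, while the
  simulator uses `round(p S)` cells; these coincide for the default
  `p = 1/2` with even `S`.
- Reduced-scale populations (~300 colonies) exaggerate drift and
  mutation load relative to the cluster-scale originals; equilibrium trait
  means remain within a few hundredths of the analytic predictions, but
  rare-event statistics (waiting times to differentiation) should only be
  read qualitatively at this scale.
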