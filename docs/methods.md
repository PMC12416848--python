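# Methods

## Model

`ecoassembly` simulates the assembly of ecological communities whose
abundance dynamics follow a generalized Lotka–Volterra system with three
interaction types. For species *i* with abundance *x_i*,

    dx_i/dt = x_i * ( r_i  -  δ·n⁺_i  -  s_i x_i
                      - Σ_j c_ij x_j
                      - Σ_j p⁻_ij x_j / (1 + h_p Σ_k p⁺_jk x_k)
                      + Σ_j p⁺_ij x_j / (1 + h_p Σ_k p⁺_ik x_k)
                      + Σ_j m_ij  x_j / (1 + h_m Σ_k m_ik x_k) )

* `c_ij ≥ 0` — competition (mutual harm; `c_ij` and `c_ji` are drawn
  independently, only the *support* is symmetric).
* `p⁺_ij / p⁻_ij ≥ 0` — consumer–resource: if *i* consumes *j* then
  `p⁺_ij > 0` and `p⁻_ji > 0`. The consumer's gain is capped at the
  resource's loss (`p⁺_ij ≤ p⁻_ji`, biomass conversion efficiency ≤ 1).
* `m_ij ≥ 0` — mutualism (symmetric support, independent weights).

Positive intake saturates via Type II functional responses: consumers and
mutualists are saturated by their **own** total intake, while a resource's
loss is saturated by its **consumer's** total intake — hence the different
denominators on the `p⁻` and `p⁺` terms. Competition needs no saturation
(it is already a mutual loss). `n⁺_i` counts the interactions that benefit
*i* (its mutualistic partners plus the resources it consumes); each one
costs `δ` off the intrinsic growth rate, an evolutionary trade-off that can
drive the effective growth rate negative for species hoarding positive
interactions.

Each unordered species pair carries **at most one** interaction type. The
model itself does not force this, but interaction-type proportions are only
well defined when pairs partition cleanly, and all link-creation rules draw
new links on unoccupied pairs only.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `sigma` | 0.2 | half-normal scale of new interaction strengths, `w = |N(0, σ²)|` |
| `delta` | 0.01 | cost per beneficial positive interaction (1/time) |
| `h_m`, `h_p` | 0.1 | saturation (handling) times |
| `x_ext` | 1e-6 | extinction threshold and introduction abundance |
| `mu_r` | 0.1 | mean intrinsic growth; `r ~ N(0.1, 0.01²)`, untruncated |
| `s` | `1 / LogNormal(0.1, 0.5)` | intraspecific competition (see below) |
| `delta_mut` (Δ) | 5 | max link differences between offspring and parent |
| `rho1, rho2` | 0.05, 0.5 | invader connectance window |
| founders | 5 linkless species, `x₀ ~ U(0, 0.02)` | initial condition |
| events | 1000 (full scale) | successful establishments per run |

The high strength-to-cost regime (`σ/δ = 20`) is the regime of interest:
it lets ecological selection favour mutualistic interactions.

The intraspecific-competition draw is `s = 1/L` with
`L ~ LogNormal(μ=0.1, σ=0.5)`, where μ and σ parameterize the *underlying
normal* — lognormal parameter conventions vary, so the package fixes this
one and tests the resulting closed form `E[1/s] = exp(0.1 + 0.5²/2)`.
Traits `r, s` are never inherited.

## Equilibration and extinction

Between assembly events the ODE is deterministic. It is integrated with
LSODA (`scipy.integrate.solve_ivp`, `rtol=1e-8`, `atol=1e-12`, analytic
Jacobian) in windows of `t_check = 10` time units. After each window,
species below `x_ext` are removed and the matrices/trait vectors shrink.
The community counts as equilibrated when the maximum relative abundance
change across one window is `< 0.01%` (`eq_rel_tol = 1e-4`) with no
extinction in that window. "Successive timesteps" is thus defined as a
fixed check window, which makes the criterion integrator-independent. A
cap `t_max = 1e5` prevents hangs on slowly-settling or cycling states; a
capped equilibration is logged and the capped state is used as the
assembly baseline rather than aborting the run.

Because the stopping rule bounds the *change per window*, not the distance
to the fixed point, the returned state is accurate to roughly `1e-4`
relative; tests that check closed-form equilibria to `1e-6` therefore
equilibrate with a tighter `eq_rel_tol`.

## Assembly

An *assembly event* is one successful species addition; rejected proposals
do not count. One origin (speciation vs invasion) is drawn per event —
in mixed scenarios by a coin with probability `p_invasion` — and proposals
of that origin are redrawn until one establishes (cap `max_proposals =
10_000`, exceeded → error naming the event, signalling an inviable regime).

**Establishment.** The resident community, at equilibrium, is augmented
with the candidate at abundance `x_ext`; the candidate is accepted iff its
instantaneous per-capita growth rate (including its `δ` cost and its own
`s·x_ext` term, and with its partners' saturation denominators updated) is
strictly positive. Accepted species enter at exactly `x_ext`.

**Speciation.** A parent is chosen uniformly (optionally proportionally to
abundance). The offspring inherits the parent's links; the number of link
differences `d` is uniform on `{1..Δ}`; a split `(n_remove, n_create)`
summing to `d` is uniform over feasible splits; removed links are uniform
without replacement and new links are placed on uniformly chosen
unoccupied partners. New-link types are uniform over the allowed menu
(competition, mutualism unless disabled, consumer role, resource role) —
uniformity imposes no bias and leaves selection to the dynamics. Every
inherited directed weight mutates as `w' = w + N(0, (0.05 w)²)`, clamped
at zero, with the consumer bound re-enforced afterwards. The parent itself
is a legal *new* partner (no automatic parent–offspring link), which also
means a lone linkless parent can still speciate; consequently the drawn
`d` is clamped to the number of removable-plus-creatable links in very
small communities.

**Invasion.** A connectance `ρ ~ U(ρ1, ρ2)` is drawn per invader; each
resident becomes a partner independently with probability ρ (binomial, not
exact-count, link number — "assigned with a probability"). Type
proportions `(q_c, q_p, q_m)` are drawn per invader: uniform on the
2-simplex (`Dirichlet(1,1,1)`) in the free mode; `q_m = 0` with `(q_c,
q_p)` uniform on the 1-simplex in the no-mutualism mode; `q_m ~ U(0.8,
1)` with the rest split equally in the high-mutualism mode. Each link's
type is a draw from `q`, consumer/resource role uniform, weights
half-normal with the consumer bound enforced.

**Switch scenarios** flip the available mutualism menu permanently after a
given event (default: the run midpoint): `switch_on` starts without
mutualism and allows it afterwards, `switch_off` the reverse. Existing
mutualistic links persist and can only be lost to extinction.

**Housekeeping.** From event 20 onward, species left with no interactions
are purged after each event (this is what ultimately removes unconnected
founders). Whole runs are bitwise reproducible from a single seed: one
`numpy` generator drives every draw.

**Fixed-interval variant.** Instead of waiting for equilibrium, events can
fire every `fixed_interval_windows` integration windows (default 10, i.e.
100 time units), modelling assembly faster than ecological relaxation. The
establishment test is unchanged.

## Stability analysis

The community matrix is the analytic Jacobian `J = diag(g) + diag(x)
∂g/∂x` of the right-hand side at the final equilibrium, with closed-form
derivatives of the Type II terms (the `δ` cost is constant in `x` and
enters only through `g` on the diagonal). Analytic construction is
preferred over finite differences for precision near `x_ext`-scale
abundances; a central-finite-difference Jacobian (per-coordinate step
`max(1e-7, 1e-4·x_i)`) serves as a cross-check in the tests. Stability is
`max Re λ < 1e-8`, the tolerance absorbing numerically-zero modes.
Extinct species are removed before the Jacobian is taken.

## Network metrics

Metrics operate on the unweighted *pair graph* (one edge per interacting
unordered pair; consumer/resource direction ignored — degree is "number of
interactions of a species"):

* connectance `C = L / (S(S-1)/2)`; complexity `S·C`;
* interaction-type proportions over realized pairs;
* degree entropy `H = −Σ_k P(k) ln P(k)` (natural log) of the empirical
  degree distribution;
* modularity `Mod = Σ_c (L_c/m − ε(k_c/2m)²)` at resolution `ε = 1`,
  maximized by seeded Louvain (best of 5 restarts, which stabilizes the
  heuristic; exhaustive partition search verifies it on ≤ 8-node graphs);
* *effective increase* of a metric: its value minus the mean over 50
  Erdős–Rényi `G(S, p=C)` draws — the part of the structure not expected
  by chance. Edgeless ER draws are skipped for modularity.

## Scenario runner

Named presets cover the scenario families: `Evo`, `Inv`, their `No-M`
controls, `Inv-High-M`, `Inv-switch-on/off`, `Mixed-0.2/0.5/0.8`,
`Evo-abundance-weighted` and `fast-assembly`. Full scale is 15 replicates
× 1000 events with metrics aggregated every 50 events (mean and standard
error = sd/√n across replicates). Replicate seeds derive from one master
seed through `numpy.random.SeedSequence(master).generate_state(n)` folded
to 31 bits. Replicate failures are recorded and excluded from aggregation
with a warning.

### Reduced-scale runs

Full-scale runs take hours. The test suite and the acceptance script use
reduced runs — 4–5 replicates of 250–300 events — which this package
treats as its standard verification scale: the qualitative orderings
(mutualism enrichment under selection, the complexity cost of removing
mutualism, the richness drop / connectance rise when mutualism invades an
assembled community, the sign of the final richness–connectance
association) are already established at a few hundred events, while
absolute curve values at 1000 events are not reproduced at this scale and
are not asserted anywhere.

## What the simulator does and does not emulate

All data are self-generated; there is no external input. The generator
realizes the study conditions (parameter defaults above), so passing tests
show internal consistency of the model and the stated trends *under those
conditions* — they say nothing about real communities' parameter ranges.
Known idealizations: deterministic dynamics between events (no demographic
noise), no spatial structure or dispersal, no trait evolution beyond
interaction rewiring, one interaction type per pair, and an establishment
rule based on instantaneous invasion growth rather than transient
survival.

## Numerical notes and edge cases

* Degenerate draws: `r_i` can be negative (untruncated normal, ~1e-24
  probability at the defaults); such species simply decay below `x_ext`.
* Inheritance noise is clamped at zero so half-normal support is
  preserved; the consumer bound is re-applied after noise.
* Zero-link invaders are legal and face establishment on
  `r − s·x_ext` alone.
* `connectance` of an `S < 2` community is defined as 0 (logged);
  `degree_entropy` of an empty graph and `modularity` of an edgeless graph
  are errors.
* Abundances are clipped at 0 inside the integrator before evaluating the
  right-hand side; extinction processing between windows is idempotent.
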