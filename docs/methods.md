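# Methods

## Model and assumptions

The package analyses the planar ODE system

    dx/dt = ( r1 - b1 x - a1 (1-m) y / ((1-m) x + k1) ) x
    dy/dt = ( r2 - a2 y / ((1-m) x + k2) ) y

on the non-negative quadrant. All eight coefficients are constants:
autonomous dynamics, no delays, no stochasticity, no harvesting, no spatial
structure. The refuge is a fixed *proportion* `m` of the prey population
(not a fixed number of individuals and not a spatial region), so the
predator interacts with `(1-m)x` prey in both the functional response and
its own carrying capacity. Densities are in arbitrary units; rates are per
unit time. No unit system is imposed beyond documentation.

Parameter domain: `r1, b1, a1, k1, r2, a2 > 0`, `k2 ≥ 0`, `0 ≤ m < 1`.
`k2 = 0` makes the predator equation singular at `x = 0`; it is therefore an
explicit opt-in (`holling_tanner=True`) rather than a silently accepted
value, and the vector field raises at the singular point instead of
returning NaN.

## Equilibrium structure

Boundary equilibria are `E0 = (0,0)`, `E1 = (r1/b1, 0)`,
`E2 = (0, r2 k2 / a2)` (with `k2 = 0`, E2 collides with the origin and is
returned flagged degenerate). Positive equilibria are the positive roots of

    a2 b1 (1-m) x² + B x + [(1-m) a1 r2 k2 - a2 r1 k1] = 0,
    B = a1 r2 (1-m)² - a2 r1 (1-m) + a2 b1 k1,

paired with the predator nullcline `y = r2((1-m)x + k2)/a2`. The case
classification (one root via the `(-B+√Δ)` formula; two roots `E3_minus <
E3_plus`; none) follows the sign pattern of `B`, the discriminant `Δ`, and
the refuge threshold `m_th = 1 - a2 r1 k1/(a1 r2 k2)`.

Numerical choices:

- **Equality events** (`m = m_th`, `Δ = 0`) are exact algebraic conditions;
  they are detected with absolute tolerance `1e-12` scaled by the magnitude
  of the compared quantities. Away from these measure-zero boundaries the
  classification is locally constant (tested by ±1e-9 jitters).
- **Quadratic roots** use the cancellation-free formulation: the
  larger-magnitude root from `q = -(B + sign(B)√Δ)/2`, the companion from
  the product of roots.
- A root at or below tolerance is treated as a boundary collision, excluded
  from the positive list and logged.
- `k2 = 0` sends `m_th → -∞`, so the one-root branch applies for every
  admissible `m`; the configuration `B ≥ 0` with `m < m_th` and `Δ > 0` is
  not covered by the case list as printed, but the root sum/product signs
  show it has no positive root — it is classified as the no-equilibrium
  case and flagged in the report.

## Stability

The authoritative verdict is the eigenvalue pair of the analytic Jacobian:
`stable` if both real parts are below `-tol`, `unstable` if any exceeds
`+tol`, else `nonhyperbolic`, with `tol = 1e-9·(1+|λ|)` (the theory's strict
inequalities give no guidance exactly at the boundary). The classical
sufficient condition — positivity of
`2 b1 (1-m) x² - (r1(1-m) - r2(1-m) - b1 k1) x + k1 r2` at a positive
equilibrium — is reported as a diagnostic and never overrides the
eigenvalues: it is sufficient only, so its failure at a hyperbolic point is
recorded as "no claim", not as instability. A randomized consistency scan
(`stability_consistency_scan`) samples parameter sets with positive equilibria
and reports verbatim any configuration where the two routes disagree or
where the smaller root `E3_minus` is not unstable; across the tested seeds
it finds none.

## Global attractivity: the iterative certificate

Under `C3: a1(1-m)² r1 r2 + a1(1-m) b1 r2 k2 < a2 b1 r1 k1` the unique
positive equilibrium attracts every positive solution. The certificate is
the monotone bounding iteration: seed with the logistic bound
`M1 = r1/b1 + ε`, feed it through the predator equation to get `M2`, feed
that back to get the prey lower bound `m1`, then `m2`, and from round 2 on
apply

    M1(n) = (r1 - a1(1-m) m2(n-1) / ((1-m) M1(n-1) + k1)) / b1 + ε/n
    M2(n) = r2((1-m) M1(n) + k2)/a2 + ε/n
    m1(n) = (r1 - a1(1-m) M2(n) / ((1-m) m1(n-1) + k1)) / b1 - ε/n
    m2(n) = r2((1-m) m1(n) + k2)/a2 - ε/n

The upper sequences are non-increasing, the lower non-decreasing, the
equilibrium always lies strictly inside the bracket, and under C3 the two
limits coincide (the uniqueness constant `D` of the limit quadratic is
negative), so the bracket collapses onto the equilibrium. The `ε/n` terms
are kept exactly as in the analytic construction, so early iterates match
it; their decay leaves the limit unaffected.

**Choice of ε.** The analysis requires ε "small enough" in two distinct
ways: (i) the strictness inequality

    (C3 margin)/(a2 b1 k1) - (a1(1-m)² r2/(a2 k1) + a1(1-m)/k1) ε > 0

must survive, and (ii) the first-round lower bounds must come out positive
and ordered. Condition (i) alone does *not* imply (ii): on the canonical
example, half the critical ε of (i) gives a negative first-round prey lower
bound. `choose_epsilon` therefore starts at half the critical value of (i)
and halves deterministically until (ii) holds — reproducible, and ε → 0 as
the C3 margin → 0.

**Why the iteration ε is capped.** The bracket width at round n is bounded
below by `ε/n` (the inflation terms are part of the recurrence), so a valid
but large ε imposes an O(ε/n) convergence floor: reaching a 1e-6 bracket
with ε ≈ 0.6 would need ~6·10⁵ rounds. Any positive ε below a valid one is
itself valid, so `iterate_bounds` defaults to `min(choose_epsilon(p), 1e-8)`:
the tail is then far below the default stopping tolerance and the
convergence rate is governed by the contraction of the comparison map
(tens of rounds on the canonical example). A user-supplied ε is used
verbatim; if it is too large the iteration surfaces a non-positive lower
bound as an error rather than masking it.

**Stopping rule.** The analysis iterates to n → ∞; numerically the loop
stops when the larger of the two bracket widths changes by less than `tol`
(default 1e-10) between rounds, or at `n_max` (default 10 000).

**Permanence.** The ε-free first-round bounds
`x̄ = r1/b1`, `ȳ = r2((1-m)x̄+k2)/a2`, `x̲ = (r1 - a1(1-m)ȳ/k1)/b1`,
`y̲ = r2((1-m)x̲+k2)/a2` are all positive under C3 and give an explicit
trapping box; trajectories are checked to enter it after a transient.

**Sister conditions.** C1 is C3 at `m = 0` (identical expression, hence
bit-identical margins); C2 is the auxiliary condition of the older
no-refuge theory, computed for reporting only — it never gates any
certificate, and a randomized search exhibits parameter sets with C1 but
not C2 whose certificate still converges, demonstrating numerically that C2
is redundant. C4 is C3 specialized to `k2 = 0`; the Holling–Tanner
certificate is the same code path, since the general formulas specialize
correctly at `k2 = 0`.

The certificate applies only in the one-equilibrium regime: C3 provably
implies the Case 1(i) configuration, so two-equilibrium parameter sets can
never reach the iteration (they fail C3 and are refused with an error, no
extrapolation attempted).

## Simulation

`solve_ivp` with LSODA, `rtol = 1e-9`, `atol = 1e-12` by default, dense
output on a configurable grid (default 501 points). The defaults keep
integrator error orders of magnitude below the 1e-3 scale at which
equilibrium convergence is judged; `t_end = 50` covers the transient of
systems with rates of order 10 and is overridable. The model is only
meaningful on the non-negative quadrant: coordinates below -1e-9 abort with
an error; excursions in (-1e-9, 0) are treated as integrator noise, clipped
to zero and flagged on the trajectory object. Initial conditions must be
strictly positive (positive solutions are the object of the attractivity
theory; the invariant axes can be studied through the equilibria/stability
modules instead).

## Randomized checks and problem sizes

Random parameter sets are drawn log-uniformly on [0.05, 10] (refuge
fraction uniform on [0, 0.9]) with seeded generators throughout; rejection
sampling selects regimes (C3 holders ≈ 46 % of draws, two-equilibrium sets
≈ 2 %). The default test suite uses 100 draws for the Jacobian
finite-difference check, 200 for the stability consistency scan, 30 for the
certificate-vs-quadratic agreement, and 20 two-equilibrium sets for the
instability of `E3_minus`; these sizes keep the whole suite under a few
seconds while giving each property multiple independent witnesses.

## What the synthetic inputs do and do not show

There is no external data: parameter sets are either the canonical worked
example or random draws from the sampler above. Passing tests therefore
establish the internal mathematics — equilibrium algebra, eigenvalue
verdicts, certificate convergence, integrator agreement — over a broad but
bounded parameter range (four orders of magnitude in rates). They say
nothing about parameter regimes outside that range, about how well this
model describes any particular field system, or about structurally
different refuge mechanisms (constant-number refuges, spatial refuges,
predator-density-dependent refuges).

## Known limitations

- No bifurcation tracking or continuation: classification is pointwise
  (plus grid sweeps); nonhyperbolic points get no center-manifold analysis.
- The attractivity certificate is one-sided: when C3 fails the package
  reports failure, it does not decide attractivity by other means (e.g.
  Lyapunov functions or the fluctuation-lemma route).
- The two-equilibrium regime gets existence and linear stability only; the
  basin structure around `E3_minus` is not computed.
- Equality-case detection (`Δ = 0`, `m = m_th`) is tolerance-based and
  cannot distinguish an exact algebraic coincidence from a near miss at the
  1e-12 level.
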