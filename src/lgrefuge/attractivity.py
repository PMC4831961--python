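"""Global-attractivity certificates via monotone iterative bounds.

The central condition is

    C3:  a1 (1-m)^2 r1 r2 + a1 (1-m) b1 r2 k2  <  a2 b1 r1 k1,

under which the system has a unique positive equilibrium attracting
every positive solution, and is in particular permanent.  The
certificate is constructive: starting from the logistic bound
x̄ = r1/b1, four sequences of ultimate upper/lower bounds for prey and
predator are built by alternately feeding each bound through the other
species' equation (a logistic comparison argument at every step).  The
upper sequences are non-increasing, the lower ones non-decreasing, the
equilibrium always lies strictly inside the bracket, and under C3 the
bracket collapses onto the equilibrium — so running the iteration *is*
the attractivity proof, executed numerically.

Each bound is inflated/deflated by ε/n, where ε > 0 must be small
enough that the strict inequality

    (a2 b1 r1 k1 - a1(1-m)^2 r1 r2 - a1(1-m) b1 r2 k2) / (a2 b1 k1)
        - (a1(1-m)^2 r2/(a2 k1) + a1(1-m)/k1) ε  >  0

survives, and additionally small enough that the first-round lower
bounds stay positive (the analytic argument needs both; the second is
the binding one in practice).  See :func:`choose_epsilon`.

Two sister conditions are tracked for comparison with the no-refuge
theory: C1 (C3 at m = 0) together with C2, an older auxiliary condition
that the iterative route proves superfluous — it is computed for
reporting only and never gates any certificate.  C4 is C3 specialized
to the Holling-Tanner case k2 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equilibria import positive_equilibria
from .model import ModelParameters, sample_parameters

__all__ = [
    "ConditionMargin",
    "ConditionReport",
    "BoundSequences",
    "CertificateError",
    "check_conditions",
    "choose_epsilon",
    "iterate_bounds",
    "permanence_bounds",
    "find_c1_without_c2",
]

#: default cap on the iteration ε: the ε/n inflation terms decay only
#: like ε/n, so a large ε (even a valid one) limits the achievable
#: bracket width at any finite n; capping at 1e-8 keeps the tail far
#: below the default convergence tolerance while every ε ≤ the cap
#: still satisfies the strictness requirements whenever C3 holds
EPSILON_CAP = 1e-8


class CertificateError(RuntimeError):
    """Raised when the attractivity hypotheses are not met."""


@dataclass(frozen=True)
class ConditionMargin:
    """A condition with its signed margin; holds iff margin > 0."""

    holds: bool
    margin: float


@dataclass(frozen=True)
class ConditionReport:
    """Margins of C1-C4 plus the no-refuge theory's constants L and M.

    C2 (and its constants M, L) belongs to the m = 0 theory of the
    no-refuge system; it is evaluated from the same formulas regardless
    of m, for comparison only.  C4 is only meaningful in the k2 = 0
    mode; its margin is reported (and flagged in ``notes``) otherwise.
    """

    c1: ConditionMargin
    c2: ConditionMargin
    c3: ConditionMargin
    c4: ConditionMargin
    L: float
    M_thm1: float
    notes: tuple[str, ...] = ()


def check_conditions(p: ModelParameters) -> ConditionReport:
    """Evaluate the four condition margins from their closed forms."""
    r1, b1, a1, k1, r2, a2, k2, om = p.r1, p.b1, p.a1, p.k1, p.r2, p.a2, p.k2, p.one_minus_m
    c1 = a2 * b1 * r1 * k1 - a1 * r1 * r2 - a1 * b1 * r2 * k2
    L = (r1 * r2 + b1 * r2 * k2) / (a2 * b1)
    M = (r1 * k1 - a1 * L) / (b1 * k1)
    c2 = 2.0 * a2 * b1 * M + (a2 * b1 * k1 - a2 * r1 - a1 * r2)
    c3 = a2 * b1 * r1 * k1 - a1 * om**2 * r1 * r2 - a1 * om * b1 * r2 * k2
    c4 = a2 * b1 * r1 * k1 - a1 * om**2 * r1 * r2
    notes = []
    if p.m != 0:
        notes.append("C1/C2 (and L, M) belong to the m=0 theory; reported for comparison")
    if k2 != 0:
        notes.append("C4 is only meaningful in the Holling-Tanner (k2=0) mode")
    return ConditionReport(
        c1=ConditionMargin(c1 > 0, c1),
        c2=ConditionMargin(c2 > 0, c2),
        c3=ConditionMargin(c3 > 0, c3),
        c4=ConditionMargin(c4 > 0, c4),
        L=L,
        M_thm1=M,
        notes=tuple(notes),
    )


def _first_round(p: ModelParameters, eps: float) -> tuple[float, float, float, float]:
    """First-round bounds (M1, M2, m1, m2) for a given ε (ε = 0 allowed)."""
    om = p.one_minus_m
    M1 = p.r1 / p.b1 + eps
    M2 = p.r2 * (om * M1 + p.k2) / p.a2 + eps
    m1 = (p.r1 - p.a1 * om * M2 / p.k1) / p.b1 - eps
    m2 = p.r2 * (om * m1 + p.k2) / p.a2 - eps
    return M1, M2, m1, m2


def _seeds_valid(p: ModelParameters, eps: float) -> bool:
    M1, M2, m1, m2 = _first_round(p, eps)
    return 0.0 < m1 <= M1 and 0.0 < m2 <= M2


def choose_epsilon(p: ModelParameters, max_halvings: int = 200) -> float:
    """A deterministic valid ε for the bounding iteration.

    Starts from half the critical value that keeps the strict
    inequality on the C3 margin alive, then halves until the four
    first-round bounds are positive and ordered (strictness of the
    margin inequality alone does not guarantee that).  As the C3 margin
    shrinks to zero the returned ε shrinks to zero with it; the
    discrete halving makes the map only piecewise monotone.

    Raises
    ------
    CertificateError
        If C3 fails (the hypothesis of the certificate) or no valid ε
        is found within ``max_halvings`` (not expected when C3 holds
        strictly).
    """
    report = check_conditions(p)
    if not report.c3.holds:
        raise CertificateError(
            f"C3 fails (margin {report.c3.margin:g} <= 0); "
            "the global-attractivity certificate does not apply"
        )
    om = p.one_minus_m
    coef = p.a1 * om**2 * p.r2 / (p.a2 * p.k1) + p.a1 * om / p.k1
    eps = 0.5 * (report.c3.margin / (p.a2 * p.b1 * p.k1)) / coef
    for _ in range(max_halvings):
        if _seeds_valid(p, eps):
            return eps
        eps *= 0.5
    raise CertificateError("could not find a valid epsilon; C3 margin may be degenerate")


def strictness_margin(p: ModelParameters, eps: float) -> float:
    """Value of the ε-strictness inequality; must be > 0 for a valid ε."""
    om = p.one_minus_m
    report = check_conditions(p)
    coef = p.a1 * om**2 * p.r2 / (p.a2 * p.k1) + p.a1 * om / p.k1
    return report.c3.margin / (p.a2 * p.b1 * p.k1) - coef * eps


@dataclass
class BoundSequences:
    """The four monotone bound sequences with their convergence record.

    ``M1``/``m1`` bracket the prey, ``M2``/``m2`` the predator, indexed
    n = 1..N.  ``limits`` holds (x̄, x̲, ȳ, y̲), the final bracket
    edges; under C3 they coincide (to tolerance) with the unique
    positive equilibrium.
    """

    epsilon: float
    M1: np.ndarray
    M2: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    converged: bool
    n_iterations: int

    @property
    def limits(self) -> tuple[float, float, float, float]:
        return (
            float(self.M1[-1]),
            float(self.m1[-1]),
            float(self.M2[-1]),
            float(self.m2[-1]),
        )


def iterate_bounds(
    p: ModelParameters,
    n_max: int = 10_000,
    tol: float = 1e-10,
    epsilon: float | None = None,
) -> BoundSequences:
    """Run the monotone bounding iteration until the bracket stabilizes.

    Round n maps the previous bracket through the model equations::

        M1(n) = (r1 - a1(1-m) m2(n-1) / ((1-m) M1(n-1) + k1)) / b1 + ε/n
        M2(n) = r2 ((1-m) M1(n) + k2) / a2 + ε/n
        m1(n) = (r1 - a1(1-m) M2(n) / ((1-m) m1(n-1) + k1)) / b1 - ε/n
        m2(n) = r2 ((1-m) m1(n) + k2) / a2 - ε/n

    seeded by the first-round logistic bounds (the n = 1 formulas with
    the full ε).  The ε/n inflation terms are kept exactly, so early
    iterates match the analytic construction; their decay makes the
    limit unaffected.  Iteration stops at ``n_max`` or when the bracket
    widths change by less than ``tol`` between rounds.

    Parameters
    ----------
    epsilon : float, optional
        Inflation ε.  Default: ``min(choose_epsilon(p), 1e-8)`` — any
        positive ε below a valid one is itself valid, and a small ε
        removes the O(ε/n) floor on the final bracket width.

    Raises
    ------
    CertificateError
        If C3 fails, or if a lower-bound entry becomes non-positive
        (signals an externally supplied ε that is too large, or a
        marginal C3; surfaced, never masked).
    """
    if epsilon is None:
        epsilon = min(choose_epsilon(p), EPSILON_CAP)
    elif epsilon <= 0:
        raise CertificateError(f"epsilon must be positive, got {epsilon!r}")
    elif not check_conditions(p).c3.holds:
        raise CertificateError("C3 fails; the certificate hypothesis is not met")
    M1, M2, m1, m2 = ([v] for v in _first_round(p, epsilon))
    if m1[0] <= 0 or m2[0] <= 0:
        raise CertificateError(
            f"first-round lower bounds not positive (m1={m1[0]:g}, m2={m2[0]:g}); "
            "epsilon too large for this parameter set"
        )
    om = p.one_minus_m
    converged = False
    for n in range(2, n_max + 1):
        e = epsilon / n
        M1n = (p.r1 - p.a1 * om * m2[-1] / (om * M1[-1] + p.k1)) / p.b1 + e
        M2n = p.r2 * (om * M1n + p.k2) / p.a2 + e
        m1n = (p.r1 - p.a1 * om * M2n / (om * m1[-1] + p.k1)) / p.b1 - e
        m2n = p.r2 * (om * m1n + p.k2) / p.a2 - e
        if m1n <= 0 or m2n <= 0:
            raise CertificateError(
                f"lower bound became non-positive at round {n} "
                f"(m1={m1n:g}, m2={m2n:g}); epsilon too large or C3 marginal"
            )
        gap_prev = max(M1[-1] - m1[-1], M2[-1] - m2[-1])
        M1.append(M1n); M2.append(M2n); m1.append(m1n); m2.append(m2n)
        gap = max(M1n - m1n, M2n - m2n)
        if abs(gap_prev - gap) < tol:
            converged = True
            break
    return BoundSequences(
        epsilon=epsilon,
        M1=np.array(M1),
        M2=np.array(M2),
        m1=np.array(m1),
        m2=np.array(m2),
        converged=converged,
        n_iterations=len(M1),
    )


def permanence_bounds(p: ModelParameters) -> tuple[float, float, float, float]:
    """Ultimate bounds (x̲, x̄, y̲, ȳ) certifying permanence under C3.

    These are the ε-free first-round bounds: every positive solution
    eventually enters and stays in the box [x̲, x̄] × [y̲, ȳ].  All
    four are positive whenever C3 holds.
    """
    report = check_conditions(p)
    if not report.c3.holds:
        raise CertificateError(
            f"C3 fails (margin {report.c3.margin:g} <= 0); permanence not certified"
        )
    M1, M2, m1, m2 = _first_round(p, 0.0)
    return m1, M1, m2, M2


def find_c1_without_c2(
    n_samples: int = 100_000, seed: int = 0
) -> tuple[ModelParameters, ConditionReport] | None:
    """Randomized search for a no-refuge parameter set with C1 but not C2.

    Such a set witnesses that the auxiliary condition C2 of the older
    no-refuge theory is superfluous: its certificate (which under m = 0
    requires only C1 = C3) still converges.  Returns the first witness
    with its condition report, or None if none is found in
    ``n_samples`` draws.
    """
    rng = np.random.default_rng(seed)
    for _ in range(n_samples):
        p = sample_parameters(rng, m_max=0.0)
        report = check_conditions(p)
        if report.c1.holds and not report.c2.holds:
            return p, report
    return None


def certificate_report(
    p: ModelParameters, n_max: int = 10_000, tol: float = 1e-10
) -> dict:
    """Full certificate as a JSON-serializable dict (used by the CLI)."""
    report = check_conditions(p)
    out: dict = {
        "conditions": {
            name: {"holds": cm.holds, "margin": cm.margin}
            for name, cm in (("C1", report.c1), ("C2", report.c2),
                             ("C3", report.c3), ("C4", report.c4))
        },
        "L": report.L,
        "M": report.M_thm1,
        "notes": list(report.notes),
    }
    if not report.c3.holds:
        out["certificate"] = None
        out["error"] = "C3 fails; no attractivity certificate"
        return out
    seq = iterate_bounds(p, n_max=n_max, tol=tol)
    x_hi, x_lo, y_hi, y_lo = seq.limits
    eqs = positive_equilibria(p)
    eq = eqs[0] if eqs else None
    out["certificate"] = {
        "epsilon": seq.epsilon,
        "n_iterations": seq.n_iterations,
        "converged": seq.converged,
        "limits": {"x_upper": x_hi, "x_lower": x_lo,
                   "y_upper": y_hi, "y_lower": y_lo},
        "equilibrium": None if eq is None else {"x": eq.x, "y": eq.y, "kind": eq.kind},
        "agreement_gap": None if eq is None else max(
            abs(x_hi - eq.x), abs(x_lo - eq.x), abs(y_hi - eq.y), abs(y_lo - eq.y)
        ),
    }
    x_lo0, x_hi0, y_lo0, y_hi0 = permanence_bounds(p)
    out["permanence_box"] = {"x": [x_lo0, x_hi0], "y": [y_lo0, y_hi0]}
    return out
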