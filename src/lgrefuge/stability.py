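"""Linearized stability of equilibria.

Two routes are provided and cross-checked.  The authoritative verdict
comes from the eigenvalues of the analytic Jacobian.  For positive
equilibria the classical sufficient condition — positivity of the
quadratic

    P(x) = 2 b1 (1-m) x^2 - (r1 (1-m) - r2 (1-m) - b1 k1) x + k1 r2

at the equilibrium — is evaluated and reported as a diagnostic; it is a
sufficient condition only, so when it fails at a hyperbolic equilibrium
the eigenvalue verdict stands and the disagreement is recorded rather
than resolved by guesswork.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibria import Equilibrium, positive_equilibria
from .model import ModelParameters, State, jacobian, sample_parameters

__all__ = [
    "StabilityVerdict",
    "ScanReport",
    "stability_of",
    "stability_polynomial",
    "stability_consistency_scan",
]

#: hyperbolicity tolerance: |Re λ| <= HYPERBOLICITY_TOL * (1 + |λ|)
#: is treated as a zero real part (nonhyperbolic)
HYPERBOLICITY_TOL = 1e-9


@dataclass(frozen=True)
class StabilityVerdict:
    """Eigenvalue-based verdict with the sufficient-condition diagnostic.

    ``label`` is ``stable`` (both real parts negative), ``unstable`` (at
    least one positive), or ``nonhyperbolic`` (a real part within
    tolerance of zero and none positive).  ``sufficient_condition_value`` is
    P(x*) for positive equilibria (None otherwise);
    ``sufficient_condition_agrees`` records whether the sign test and the eigenvalue
    test agree where the sign test applies.
    """

    label: str
    eigenvalues: tuple[complex, complex]
    sufficient_condition_value: float | None = None
    sufficient_condition_agrees: bool | None = None


def stability_polynomial(p: ModelParameters, x: float) -> float:
    """Evaluate the stability quadratic P at prey coordinate x."""
    om = p.one_minus_m
    return (
        2.0 * p.b1 * om * x**2
        - (p.r1 * om - p.r2 * om - p.b1 * p.k1) * x
        + p.k1 * p.r2
    )


def _label(eigs: np.ndarray, tol: float) -> str:
    re = eigs.real
    thresh = tol * (1.0 + np.abs(eigs))
    if np.any(re > thresh):
        return "unstable"
    if np.all(re < -thresh):
        return "stable"
    return "nonhyperbolic"


def stability_of(
    p: ModelParameters, e: Equilibrium, tol: float = HYPERBOLICITY_TOL
) -> StabilityVerdict:
    """Stability verdict at an equilibrium produced by the equilibria module."""
    eigs = np.linalg.eigvals(jacobian(p, State(e.x, e.y)))
    label = _label(eigs, tol)
    if not e.is_positive:
        return StabilityVerdict(label, (complex(eigs[0]), complex(eigs[1])))
    value = stability_polynomial(p, e.x)
    # the sign test is sufficient for stability only; agreement is
    # checked where it makes a claim (value > 0 => stable)
    agrees = None
    if value > 0 and label != "nonhyperbolic":
        agrees = label == "stable"
    return StabilityVerdict(
        label, (complex(eigs[0]), complex(eigs[1])), value, agrees
    )


@dataclass
class ScanReport:
    """Outcome of a randomized consistency scan over parameter space."""

    n_samples: int
    n_with_positive: int = 0
    n_case2: int = 0
    counterexamples: list[dict] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.counterexamples


def stability_consistency_scan(
    n_samples: int,
    seed: int,
    extra_params: list[ModelParameters] | None = None,
) -> ScanReport:
    """Randomized cross-check of the two stability routes.

    Samples parameter sets with at least one positive equilibrium and
    asserts (a) the smaller root E3_minus of the two-equilibria case is
    always eigenvalue-unstable and (b) wherever the sufficient-condition
    quadratic is positive at E3_1 or E3_plus, the eigenvalue test says
    stable.  Any counterexample configuration is reported verbatim.
    ``extra_params`` forces specific parameter sets into the scan.
    """
    report = ScanReport(n_samples=n_samples)
    if n_samples <= 0 and not extra_params:
        return report
    rng = np.random.default_rng(seed)

    def has_positive(p: ModelParameters) -> bool:
        return bool(positive_equilibria(p))

    samples = list(extra_params or [])
    for _ in range(n_samples):
        samples.append(sample_parameters(rng, predicate=has_positive))
    for p in samples:
        eqs = positive_equilibria(p)
        if not eqs:
            continue
        report.n_with_positive += 1
        if any(e.kind == "E3_minus" for e in eqs):
            report.n_case2 += 1
        for e in eqs:
            v = stability_of(p, e)
            if e.kind == "E3_minus" and v.label != "unstable":
                report.counterexamples.append(
                    {"check": "E3_minus_unstable", "params": p.to_dict(),
                     "equilibrium": (e.x, e.y), "verdict": v.label}
                )
            if e.kind in ("E3_1", "E3_plus") and v.sufficient_condition_agrees is False:
                report.counterexamples.append(
                    {"check": "sufficient_condition_vs_eigenvalues",
                     "params": p.to_dict(), "equilibrium": (e.x, e.y),
                     "P_value": v.sufficient_condition_value, "verdict": v.label}
                )
    return report
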