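"""Equilibrium structure of the refuge-modified Leslie-Gower system.

Positive equilibria are intersections of the prey nullcline
``r1 - b1 x = a1 (1-m) y / ((1-m) x + k1)`` with the predator nullcline
``y = r2 ((1-m) x + k2) / a2``.  Eliminating ``y`` gives a quadratic in
``x``,

    a2 b1 (1-m) x^2 + B x + [(1-m) a1 r2 k2 - a2 r1 k1] = 0,

with ``B = a1 r2 (1-m)^2 - a2 r1 (1-m) + a2 b1 k1`` and discriminant
``Delta = B^2 - 4 (1-m) a2 b1 [(1-m) a1 r2 k2 - a2 r1 k1]``.  The sign
pattern of ``B``, ``Delta`` and the refuge threshold
``m_th = 1 - a2 r1 k1 / (a1 r2 k2)`` classifies the number of positive
equilibria into the three existence cases:

* Case 1 (one positive equilibrium, E3_1):
  (i) m > m_th;  (ii) m = m_th and B < 0;
  (iii) m < m_th, B < 0 and Delta = 0.
* Case 2 (two positive equilibria E3_minus < E3_plus):
  m < m_th, B < 0, Delta > 0.
* Case 3 (none): otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .model import ModelParameters

__all__ = [
    "DiscriminantData",
    "Equilibrium",
    "CaseClassification",
    "compute_discriminants",
    "boundary_equilibria",
    "positive_equilibria",
    "classify_case",
    "predator_nullcline_y",
]

logger = logging.getLogger(__name__)

#: absolute tolerance (scaled by magnitude) for the exact algebraic
#: events m = m_threshold and Delta = 0 of the case classification
EQUALITY_TOL = 1e-12


@dataclass(frozen=True)
class DiscriminantData:
    """The algebra behind existence of positive equilibria.

    ``B`` and ``Delta`` are the linear coefficient and discriminant of
    the equilibrium quadratic; ``D`` is the constant term of the
    uniqueness quadratic used in the global-attractivity argument
    (negative whenever the attractivity condition holds, ruling out two
    distinct limits of the bounding sequences); ``m_threshold`` is the
    refuge fraction above which the predator-only equilibrium loses
    stability and a unique positive equilibrium exists (undefined, None,
    when k2 = 0 since it diverges to -inf).
    """

    B: float
    Delta: float
    D: float
    m_threshold: float | None


@dataclass(frozen=True)
class Equilibrium:
    """A labeled fixed point of the system.

    ``kind`` is one of E0 (extinction), E1 (prey only), E2 (predator
    only), E3_1 (unique positive), E3_plus / E3_minus (larger / smaller
    positive root in the two-equilibria case).  ``degenerate`` flags the
    k2 = 0 collision of E2 with the origin.  ``diagnostics`` carries
    stability data when attached by the stability module.
    """

    x: float
    y: float
    kind: str
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def is_positive(self) -> bool:
        return self.kind.startswith("E3")


@dataclass(frozen=True)
class CaseClassification:
    """Existence-case label with the implied count of positive equilibria."""

    case_label: str  # CASE1_i | CASE1_ii | CASE1_iii | CASE2 | CASE3
    n_positive: int
    flags: tuple[str, ...] = ()


def compute_discriminants(p: ModelParameters) -> DiscriminantData:
    """Compute B, Delta, D and the refuge threshold from closed forms."""
    om = p.one_minus_m
    B = p.a1 * p.r2 * om**2 - p.a2 * p.r1 * om + p.a2 * p.b1 * p.k1
    Delta = B**2 - 4.0 * om * p.a2 * p.b1 * (om * p.a1 * p.r2 * p.k2 - p.a2 * p.r1 * p.k1)
    D = p.a2 * (
        p.a1 * om**2 * p.r1 * p.r2 + p.a1 * om * p.b1 * p.r2 * p.k2 - p.a2 * p.b1 * p.r1 * p.k1
    ) + p.a1 * p.r2 * om * (p.a1 * p.r2 * om**2 - p.a2 * p.b1 * p.k1)
    if p.k2 == 0:
        m_threshold = None
    else:
        m_threshold = 1.0 - p.a2 * p.r1 * p.k1 / (p.a1 * p.r2 * p.k2)
    return DiscriminantData(B=B, Delta=Delta, D=D, m_threshold=m_threshold)


def predator_nullcline_y(p: ModelParameters, x: float) -> float:
    """Predator nullcline y = r2((1-m)x + k2)/a2 at prey density x."""
    return p.r2 * (p.one_minus_m * x + p.k2) / p.a2


def boundary_equilibria(p: ModelParameters) -> list[Equilibrium]:
    """The three boundary equilibria E0=(0,0), E1=(r1/b1,0), E2=(0, r2 k2/a2).

    With k2 = 0, E2 coincides with the origin; it is still returned,
    labeled E2 with ``degenerate=True``.
    """
    e0 = Equilibrium(0.0, 0.0, "E0")
    e1 = Equilibrium(p.r1 / p.b1, 0.0, "E1")
    y2 = p.r2 * p.k2 / p.a2
    e2 = Equilibrium(0.0, y2, "E2", degenerate=(p.k2 == 0))
    return [e0, e1, e2]


def _is_zero(value: float, scale: float, tol: float) -> bool:
    return abs(value) <= tol * max(1.0, abs(scale))


def classify_case(p: ModelParameters, tol: float = EQUALITY_TOL) -> CaseClassification:
    """Classify the existence case for positive equilibria.

    Equality events (m = m_threshold, Delta = 0) are exact algebraic
    conditions; they are detected with absolute tolerance ``tol`` scaled
    by the magnitude of the compared quantities.  With k2 = 0 the
    threshold diverges to -inf, so any admissible m exceeds it and the
    Case 1(i) branch applies.
    """
    d = compute_discriminants(p)
    if d.m_threshold is None:
        return CaseClassification("CASE1_i", 1)
    mt = d.m_threshold
    m_eq = _is_zero(p.m - mt, mt, tol)
    delta_scale = d.B**2 + abs(d.Delta - d.B**2)  # magnitudes entering Delta
    delta_zero = _is_zero(d.Delta, delta_scale, tol)
    if not m_eq and p.m > mt:
        return CaseClassification("CASE1_i", 1)
    if m_eq and d.B < 0:
        return CaseClassification("CASE1_ii", 1)
    if not m_eq and p.m < mt and d.B < 0:
        if delta_zero:
            return CaseClassification("CASE1_iii", 1)
        if d.Delta > 0:
            return CaseClassification("CASE2", 2)
        return CaseClassification("CASE3", 0)
    flags: tuple[str, ...] = ()
    if not m_eq and p.m < mt and d.B >= 0 and d.Delta > 0:
        # Not covered by the printed case list; the algebra gives root
        # sum <= 0 with root product > 0, so no positive root exists and
        # CASE3 is correct — flagged for visibility all the same.
        flags = ("B_nonnegative_below_threshold",)
    return CaseClassification("CASE3", 0, flags=flags)


def _quadratic_roots(p: ModelParameters, d: DiscriminantData) -> tuple[float, float]:
    """Both real roots of the equilibrium quadratic, numerically stable.

    Computes the larger-magnitude root first via q = -(B + sign(B)√Δ)/2,
    then its companion from the product of roots, avoiding cancellation
    when B and √Δ nearly cancel.  Requires Delta >= 0 (clipped at 0).
    """
    a = p.a2 * p.b1 * p.one_minus_m
    c = p.one_minus_m * p.a1 * p.r2 * p.k2 - p.a2 * p.r1 * p.k1
    sqrt_delta = math.sqrt(max(d.Delta, 0.0))
    if d.B == 0:
        r = sqrt_delta / (2.0 * a)
        return -r, r
    q = -0.5 * (d.B + math.copysign(sqrt_delta, d.B))
    return q / a, (c / q if q != 0 else 0.0)


def positive_equilibria(
    p: ModelParameters, tol: float = EQUALITY_TOL
) -> list[Equilibrium]:
    """Positive equilibria per the existence case, with nullcline y.

    Returns one equilibrium labeled ``E3_1`` in Case 1, the pair
    ``E3_minus``, ``E3_plus`` (ordered by x) in Case 2, and an empty
    list in Case 3.  A root at or below ``tol`` is a boundary collision:
    it is excluded from the list and logged.
    """
    cls = classify_case(p, tol=tol)
    if cls.n_positive == 0:
        return []
    d = compute_discriminants(p)
    roots = _quadratic_roots(p, d)
    if cls.case_label.startswith("CASE1"):
        x = max(roots)  # the (-B + √Δ)/(2(1-m)a2 b1) root
        candidates = [(x, "E3_1")]
    else:
        x_minus, x_plus = sorted(roots)
        candidates = [(x_minus, "E3_minus"), (x_plus, "E3_plus")]
    out = []
    for x, kind in candidates:
        if x <= tol * max(1.0, abs(x)):
            logger.warning(
                "positive-case root x=%g at or below tolerance; excluded as a "
                "boundary collision (case %s)", x, cls.case_label,
            )
            continue
        out.append(Equilibrium(x, predator_nullcline_y(p, x), kind))
    return out
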