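"""Core model definition: parameters, state, vector field, Jacobian.

The model is a two-species Leslie-Gower predator-prey system with a
Holling type II functional response and a constant-proportion prey
refuge.  A fixed fraction ``m`` of the prey population is protected
from predation, so only ``(1 - m) x`` prey are available to the
predator:

.. math::

    \\dot x = \\left( r_1 - b_1 x
              - \\frac{a_1 (1-m) y}{(1-m) x + k_1} \\right) x, \\qquad
    \\dot y = \\left( r_2 - \\frac{a_2 y}{(1-m) x + k_2} \\right) y.

The predator grows logistically with a carrying capacity proportional
to the available prey (the Leslie-Gower term); ``k_1`` and ``k_2``
measure the environmental protection afforded to prey and predator
respectively.  Setting ``m = 0`` removes the refuge; setting
``k_2 = 0`` gives the Holling-Tanner model in which the predator has
no alternate food (an explicit opt-in mode, since the predator
equation is then singular at ``x = 0``).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "ModelParameters",
    "State",
    "ParameterError",
    "StateError",
    "validate_parameters",
    "vector_field",
    "jacobian",
    "rhs",
    "load_parameters",
    "sample_parameters",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates the model's domain."""


class StateError(ValueError):
    """Raised for invalid states or evaluation at a singular point."""


_PARAM_FIELDS = ("r1", "b1", "a1", "k1", "r2", "a2", "k2", "m")


@dataclass(frozen=True)
class ModelParameters:
    """The eight coefficients of the refuge-modified Leslie-Gower system.

    Parameters
    ----------
    r1 : float
        Prey intrinsic growth rate (1/time, > 0).
    b1 : float
        Prey intraspecific competition strength (> 0); ``r1/b1`` is the
        prey carrying capacity in the absence of predation.
    a1 : float
        Maximum per-capita prey reduction rate attainable by the
        predator (> 0).
    k1 : float
        Environmental protection constant for the prey (density, > 0);
        half-saturation constant of the functional response.
    r2 : float
        Predator intrinsic growth rate (> 0).
    a2 : float
        Measure of the food quantity the prey provides, converted to
        predator birth (> 0).
    k2 : float
        Environmental protection constant for the predator (>= 0);
        ``k2 = 0`` only with ``holling_tanner=True``.
    m : float
        Refuge fraction in ``[0, 1)``: the proportion of prey protected
        from predation.
    holling_tanner : bool, optional
        Opt-in gate for the ``k2 = 0`` (no alternate predator food)
        mode.  Default False.
    """

    r1: float
    b1: float
    a1: float
    k1: float
    r2: float
    a2: float
    k2: float
    m: float
    holling_tanner: bool = False

    def __post_init__(self) -> None:
        for name in ("r1", "b1", "a1", "k1", "r2", "a2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ParameterError(
                    f"parameter {name} must be finite and strictly positive, got {v!r}"
                )
        if not (math.isfinite(self.k2) and self.k2 >= 0):
            raise ParameterError(f"parameter k2 must be finite and >= 0, got {self.k2!r}")
        if not (math.isfinite(self.m) and 0 <= self.m < 1):
            raise ParameterError(f"refuge fraction m must lie in [0, 1), got {self.m!r}")
        if self.k2 == 0 and not self.holling_tanner:
            raise ParameterError(
                "k2 = 0 makes the predator equation singular at x = 0; "
                "pass holling_tanner=True to opt into the Holling-Tanner mode"
            )
        if self.k2 > 0 and self.holling_tanner:
            raise ParameterError("holling_tanner mode requires k2 = 0")

    @property
    def one_minus_m(self) -> float:
        return 1.0 - self.m

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in _PARAM_FIELDS}
        if self.holling_tanner:
            d["holling_tanner"] = True
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        unknown = set(d) - set(_PARAM_FIELDS) - {"holling_tanner"}
        if unknown:
            raise ParameterError(f"unknown parameter field(s): {sorted(unknown)}")
        missing = set(_PARAM_FIELDS) - set(d)
        if missing:
            raise ParameterError(f"missing parameter field(s): {sorted(missing)}")
        return cls(**{k: (bool(v) if k == "holling_tanner" else float(v)) for k, v in d.items()})


@dataclass(frozen=True)
class State:
    """A point (x, y) in the non-negative phase quadrant.

    ``x`` is prey density, ``y`` is predator density.  Boundary states
    (either coordinate zero) are valid: the axes are invariant and their
    dynamics are meaningful.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        for name in ("x", "y"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise StateError(f"state coordinate {name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


def validate_parameters(p: ModelParameters) -> ModelParameters:
    """Return ``p`` unchanged if all domain invariants hold.

    ``ModelParameters`` validates on construction; this re-runs the
    checks (useful after ``object.__setattr__``-style tampering or for
    plain dict input via :meth:`ModelParameters.from_dict`).
    """
    if not isinstance(p, ModelParameters):
        raise ParameterError(f"expected ModelParameters, got {type(p).__name__}")
    p.__post_init__()
    return p


def _denominators(p: ModelParameters, x: float) -> tuple[float, float]:
    om = p.one_minus_m
    d1 = om * x + p.k1
    d2 = om * x + p.k2
    if d2 == 0.0:
        raise StateError(
            "predator interaction denominator (1-m)x + k2 is zero "
            f"(k2={p.k2}, x={x}); the Holling-Tanner mode is singular at x = 0"
        )
    return d1, d2


def vector_field(p: ModelParameters, s: State) -> tuple[float, float]:
    """Evaluate (dx/dt, dy/dt) of the refuge-modified system at ``s``.

    Raises
    ------
    StateError
        If a denominator vanishes (possible only with ``k2 = 0`` at
        ``x = 0``).
    """
    x, y = s.x, s.y
    om = p.one_minus_m
    d1, d2 = _denominators(p, x)
    dx = (p.r1 - p.b1 * x - p.a1 * om * y / d1) * x
    dy = (p.r2 - p.a2 * y / d2) * y
    return dx, dy


def jacobian(p: ModelParameters, s: State) -> np.ndarray:
    """Analytic Jacobian of the vector field at ``s`` (2x2 array).

    Entries (f is the prey equation, g the predator equation)::

        df/dx = r1 - 2 b1 x - a1 (1-m) k1 y / ((1-m)x + k1)^2
        df/dy = -a1 (1-m) x / ((1-m)x + k1)
        dg/dx = a2 (1-m) y^2 / ((1-m)x + k2)^2
        dg/dy = r2 - 2 a2 y / ((1-m)x + k2)
    """
    x, y = s.x, s.y
    om = p.one_minus_m
    d1, d2 = _denominators(p, x)
    j11 = p.r1 - 2.0 * p.b1 * x - p.a1 * om * p.k1 * y / d1**2
    j12 = -p.a1 * om * x / d1
    j21 = p.a2 * om * y**2 / d2**2
    j22 = p.r2 - 2.0 * p.a2 * y / d2
    return np.array([[j11, j12], [j21, j22]], dtype=float)


def rhs(p: ModelParameters) -> Callable[[float, np.ndarray], np.ndarray]:
    """Return an ODE right-hand side ``f(t, z)`` for scipy integrators.

    The returned callable evaluates the raw rational expressions without
    State validation (integrators may probe slightly negative values;
    positivity is enforced by the caller on the solution, not here).
    """
    r1, b1, a1, k1, r2, a2, k2 = p.r1, p.b1, p.a1, p.k1, p.r2, p.a2, p.k2
    om = p.one_minus_m

    def f(t: float, z: np.ndarray) -> np.ndarray:
        x, y = z
        d1 = om * x + k1
        d2 = om * x + k2
        return np.array(
            [(r1 - b1 * x - a1 * om * y / d1) * x, (r2 - a2 * y / d2) * y]
        )

    return f


def load_parameters(path: str | Path) -> ModelParameters:
    """Read parameters from a flat JSON or YAML config file.

    The schema is the eight field names plus an optional boolean
    ``holling_tanner``.  The format is chosen by extension
    (``.json`` vs ``.yml``/``.yaml``); anything else is tried as JSON
    first, then YAML.
    """
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    if suffix == ".json":
        data = json.loads(text)
    elif suffix in (".yml", ".yaml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} must contain a flat mapping")
    return ModelParameters.from_dict(data)


def sample_parameters(
    rng: np.random.Generator,
    *,
    low: float = 0.05,
    high: float = 10.0,
    m_max: float = 0.9,
    predicate: Callable[[ModelParameters], bool] | None = None,
    max_tries: int = 100_000,
) -> ModelParameters:
    """Draw a random valid parameter set, optionally rejection-sampled.

    Rates and densities are log-uniform on [low, high]; the refuge
    fraction is uniform on [0, m_max].  Used by the consistency scans
    and property tests; not part of the scientific surface.
    """
    lo, hi = math.log(low), math.log(high)
    for _ in range(max_tries):
        r1, b1, a1, k1, r2, a2, k2 = np.exp(rng.uniform(lo, hi, size=7))
        m = float(rng.uniform(0.0, m_max))
        p = ModelParameters(r1=r1, b1=b1, a1=a1, k1=k1, r2=r2, a2=a2, k2=k2, m=m)
        if predicate is None or predicate(p):
            return p
    raise RuntimeError(f"no parameter set satisfying the predicate in {max_tries} draws")
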