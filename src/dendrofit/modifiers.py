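"""Unit-interval response functions ("modifiers") for multiplicative growth models.

A modifier maps a covariate (tree size, stand basal area, a seasonal
precipitation sum or temperature mean) to a dimensionless value in [0, 1]
that scales maximum potential growth.  Six families are provided:

``logistic``
    f(x) = 1 / (1 + (x/a)^b).  Hill form: ``a`` is the half-saturation
    point (f(a) = 0.5); ``b < 0`` gives a response increasing to an
    asymptote of 1, ``b > 0`` a decreasing one.  Domain x > 0.
``modified_gaussian``
    f(x) = exp(-0.5 ((x - a)/b)^2).  Bell curve peaking at ``a``.
``negative_exponential``
    f(x) = a * exp(b x), with intercept ``a`` in (0, 1] and ``b <= 0``
    so the response decays from ``a`` at x = 0.  The canonical
    competition response: growth declines exponentially with crowding.
``negative_potential``
    f(x) = min(1, a * x^b), x >= 0.1 (the power law diverges at the
    origin for b < 0, so small covariate values are rejected).
``log_normal``
    f(x) = exp(-0.5 (ln(x/a)/b)^2), x > 0.  Skewed bell peaking at ``a``.
``modified_laplace``
    f(x) = exp(-b |x - a|), ``b >= 0``.  Sharply peaked response with
    optimum ``a`` and exponential decay on either side — the shape
    selected for the temperature response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Modifier", "FAMILIES", "eval_family"]

#: smallest admissible covariate for the x**b power-law family
_POTENTIAL_XMIN = 0.1


def _logistic(x, a, b):
    return 1.0 / (1.0 + (x / a) ** b)


def _modified_gaussian(x, a, b):
    return np.exp(-0.5 * ((x - a) / b) ** 2)


def _negative_exponential(x, a, b):
    return a * np.exp(b * x)


def _negative_potential(x, a, b):
    return np.minimum(1.0, a * x**b)


def _log_normal(x, a, b):
    return np.exp(-0.5 * (np.log(x / a) / b) ** 2)


def _modified_laplace(x, a, b):
    return np.exp(-b * np.abs(x - a))


FAMILIES = {
    "logistic": _logistic,
    "modified_gaussian": _modified_gaussian,
    "negative_exponential": _negative_exponential,
    "negative_potential": _negative_potential,
    "log_normal": _log_normal,
    "modified_laplace": _modified_laplace,
}

#: families whose algebra requires a strictly positive covariate
_POSITIVE_X = {"logistic", "negative_potential", "log_normal"}


def _validate(family: str, a: float, b: float) -> None:
    if family not in FAMILIES:
        raise ValueError(
            f"unknown modifier family {family!r}; choose from {sorted(FAMILIES)}"
        )
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError(f"{family}: parameters must be finite, got a={a}, b={b}")
    if family in ("logistic", "log_normal", "negative_potential") and a <= 0:
        raise ValueError(f"{family}: location parameter a must be > 0, got {a}")
    if family == "negative_exponential":
        if not (0.0 < a <= 1.0):
            raise ValueError(
                f"negative_exponential: intercept a must lie in (0, 1], got {a}"
            )
        if b > 0:
            raise ValueError(
                "negative_exponential: b must be <= 0 (decreasing response); "
                f"got b={b} which exceeds 1 for large x"
            )
    if family == "negative_potential" and a <= 0:
        raise ValueError(f"negative_potential: a must be > 0, got {a}")
    if family == "modified_laplace" and b < 0:
        raise ValueError(
            f"modified_laplace: decay rate b must be >= 0, got {b} "
            "(negative b exceeds 1 away from the optimum)"
        )
    if family in ("modified_gaussian", "log_normal") and b == 0:
        raise ValueError(f"{family}: width parameter b must be nonzero")


def eval_family(family: str, x, a: float, b: float):
    """Evaluate one family without constructing a :class:`Modifier`.

    Fast path used inside likelihood loops; performs domain checks but
    assumes parameters were validated once up front.
    """
    x = np.asarray(x, dtype=float)
    if family in _POSITIVE_X:
        xmin = _POTENTIAL_XMIN if family == "negative_potential" else 0.0
        if np.any(x <= 0.0) or (family == "negative_potential" and np.any(x < xmin)):
            bad = x[(x <= 0.0) | (x < xmin)] if family == "negative_potential" else x[x <= 0]
            raise ValueError(
                f"{family}: covariate must be "
                f"{'>= 0.1' if family == 'negative_potential' else '> 0'}; "
                f"offending values {bad[:5]!r}"
            )
    return FAMILIES[family](x, a, b)


@dataclass(frozen=True)
class Modifier:
    """One response function: a family name plus its (a, b) parameters.

    Parameters
    ----------
    family : str
        One of the six family names in :data:`FAMILIES`.
    a : float
        Location-type parameter: half-saturation point (logistic),
        optimum (gaussian, log-normal, laplace) or intercept
        (negative exponential / potential).  Units of the covariate,
        or unitless for intercepts.
    b : float
        Shape/scale parameter; sign conventions are family-specific
        and validated at construction.
    """

    family: str
    a: float
    b: float

    def __post_init__(self) -> None:
        _validate(self.family, self.a, self.b)

    def __call__(self, x):
        """Evaluate the modifier at covariate value(s) ``x`` (in [0, 1])."""
        out = eval_family(self.family, x, self.a, self.b)
        return float(out) if np.isscalar(x) else out

    def replace(self, **kwargs) -> "Modifier":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)
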