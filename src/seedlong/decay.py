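"""Candidate viability-decay curves and quantities derived from them in closed form.

A seed lot's viability under accelerated aging is modelled as a monotone
non-increasing function ``v(t)`` of aging time ``t`` (days), with viability
expressed as a fraction in [0, 1].  Four curve families are supported:

``weibull3``
    ``v(t) = exp(-(((t - c) / lambda)) ** k)`` for ``t >= c`` and 1 below
    ``c``; scale ``lambda`` (days), shape ``k`` (dimensionless), location
    ``c`` (days, may be negative).  This is the headline model: the location
    parameter lets the curve shoulder before its drop, which captures the
    asymmetric two-phase decline seen in accelerated-aging assays.
``weibull2``
    The same curve with ``c`` fixed at 0 (nested in ``weibull3``).
``logistic``
    ``v(t) = A / (1 + exp(r * (t - m)))``, decreasing form, with asymptote
    ``A`` in (0, 1], midpoint ``m`` (days) and rate ``r`` (per day).
``gompertz``
    ``v(t) = A * exp(-b * exp(g * t))``, decreasing form, with asymptote
    ``A`` in (0, 1], displacement ``b > 0`` and rate ``g`` (per day).

The comparative-longevity summary of a curve is its L50: the time at which
viability crosses 0.5.  For lots already below 50% viability at ``t = 0``
the L50 is clamped to 0 and flagged not estimable ("n.e.").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ParameterDomainError

__all__ = [
    "DecayParams",
    "viability",
    "l50_closed_form",
    "curve_registry",
    "FAMILIES",
]

_LN2 = math.log(2.0)
# exponent clip keeping exp() finite in double precision
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class DecayParams:
    """A parameterised viability-decay curve.

    Parameters
    ----------
    family : str
        One of ``weibull3``, ``weibull2``, ``logistic``, ``gompertz``.
    values : tuple of float
        Ordered parameters of the family (see module docstring).
    """

    family: str
    values: tuple

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterDomainError(
                f"unknown family {self.family!r}; expected one of {sorted(FAMILIES)}"
            )
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", values)
        spec = FAMILIES[self.family]
        if len(values) != spec.n_params:
            raise ParameterDomainError(
                f"{self.family} takes {spec.n_params} parameters, got {len(values)}"
            )
        spec.validate(values)

    @property
    def n_params(self) -> int:
        return FAMILIES[self.family].n_params

    @property
    def names(self) -> tuple:
        return FAMILIES[self.family].param_names

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values))


def _validate_weibull(values):
    lam, k = values[0], values[1]
    if not (lam > 0):
        raise ParameterDomainError(f"Weibull scale lambda must be > 0, got {lam}")
    if not (k > 0):
        raise ParameterDomainError(f"Weibull shape k must be > 0, got {k}")


def _validate_logistic(values):
    A, _m, r = values
    if not (0 < A <= 1):
        raise ParameterDomainError(f"logistic asymptote A must be in (0, 1], got {A}")
    if not (r > 0):
        raise ParameterDomainError(f"logistic rate r must be > 0, got {r}")


def _validate_gompertz(values):
    A, b, g = values
    if not (0 < A <= 1):
        raise ParameterDomainError(f"Gompertz asymptote A must be in (0, 1], got {A}")
    if not (b > 0):
        raise ParameterDomainError(f"Gompertz displacement b must be > 0, got {b}")
    if not (g > 0):
        raise ParameterDomainError(f"Gompertz rate g must be > 0, got {g}")


def _weibull_v(t, lam, k, c):
    t = np.asarray(t, dtype=float)
    z = (t - c) / lam
    # v = exp(-z**k) for z > 0; exactly 1 at and below the location c.
    out = np.ones_like(z)
    pos = z > 0
    if np.any(pos):
        logz = np.log(z[pos])
        expo = np.exp(np.clip(k * logz, -_EXP_CLIP, _EXP_CLIP))
        out[pos] = np.exp(-expo)
    return out


def _weibull3_v(t, values):
    lam, k, c = values
    return _weibull_v(t, lam, k, c)


def _weibull2_v(t, values):
    lam, k = values
    return _weibull_v(t, lam, k, 0.0)


def _logistic_v(t, values):
    A, m, r = values
    t = np.asarray(t, dtype=float)
    return A / (1.0 + np.exp(np.clip(r * (t - m), -_EXP_CLIP, _EXP_CLIP)))


def _gompertz_v(t, values):
    A, b, g = values
    t = np.asarray(t, dtype=float)
    inner = b * np.exp(np.clip(g * t, -_EXP_CLIP, _EXP_CLIP))
    return A * np.exp(-np.clip(inner, 0.0, _EXP_CLIP))


def _weibull3_l50(values):
    lam, k, c = values
    return c + lam * _LN2 ** (1.0 / k)


def _weibull2_l50(values):
    lam, k = values
    return lam * _LN2 ** (1.0 / k)


def _logistic_l50(values):
    A, m, r = values
    if A <= 0.5:
        return -math.inf
    return m + math.log(2.0 * A - 1.0) / r


def _gompertz_l50(values):
    A, b, g = values
    if A <= 0.5:
        return -math.inf
    return math.log(math.log(2.0 * A) / b) / g


@dataclass(frozen=True)
class FamilySpec:
    """Registry entry for one decay-curve family."""

    name: str
    param_names: tuple
    n_params: int
    # default box bounds used by the fitter (lower, upper) per parameter;
    # the upper bound on a Weibull location is tightened to the first
    # observation time at fit time.
    default_bounds: tuple
    evaluate: Callable
    l50: Callable
    validate: Callable


FAMILIES = {
    "weibull3": FamilySpec(
        name="weibull3",
        param_names=("lambda", "k", "c"),
        n_params=3,
        default_bounds=((1e-3, 1e4), (1e-2, 1e4), (-1e4, 1e4)),
        evaluate=_weibull3_v,
        l50=_weibull3_l50,
        validate=_validate_weibull,
    ),
    "weibull2": FamilySpec(
        name="weibull2",
        param_names=("lambda", "k"),
        n_params=2,
        default_bounds=((1e-3, 1e4), (1e-2, 1e4)),
        evaluate=_weibull2_v,
        l50=_weibull2_l50,
        validate=_validate_weibull,
    ),
    "logistic": FamilySpec(
        name="logistic",
        param_names=("A", "m", "r"),
        n_params=3,
        default_bounds=((1e-6, 1.0), (-1e3, 1e4), (1e-6, 1e3)),
        evaluate=_logistic_v,
        l50=_logistic_l50,
        validate=_validate_logistic,
    ),
    "gompertz": FamilySpec(
        name="gompertz",
        param_names=("A", "b", "g"),
        n_params=3,
        default_bounds=((1e-6, 1.0), (1e-9, 1e6), (1e-6, 1e3)),
        evaluate=_gompertz_v,
        l50=_gompertz_l50,
        validate=_validate_gompertz,
    ),
}


def _as_params(params, family=None) -> DecayParams:
    if isinstance(params, DecayParams):
        return params
    if family is None:
        raise ParameterDomainError("family required when passing bare parameter values")
    return DecayParams(family, tuple(params))


def viability(t, params, family=None):
    """Evaluate a decay curve at time(s) ``t`` (days).

    Parameters
    ----------
    t : float or array-like
        Aging time(s) in days; must be finite.
    params : DecayParams or sequence of float
        Curve parameters.  A bare sequence requires ``family``.

    Returns
    -------
    float or ndarray
        Viability fraction(s) in [0, 1]; scalar input yields a scalar.
    """
    p = _as_params(params, family)
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ParameterDomainError("time values must be finite")
    out = FAMILIES[p.family].evaluate(t_arr, p.values)
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def l50_closed_form(params, family=None):
    """Time (days) at which a decay curve crosses 50% viability.

    Returns
    -------
    (l50, estimable) : tuple of (float, bool)
        The crossing time, clamped to 0 when the curve is already at or
        below 50% viability at ``t = 0`` (flagged not estimable, mirroring
        the "0 n.e." reporting convention for collapsed lots) or when the
        curve never reaches 0.5 (asymptote below one half).
    """
    p = _as_params(params, family)
    raw = FAMILIES[p.family].l50(p.values)
    if not math.isfinite(raw) or raw < 0:
        return 0.0, False
    return float(raw), True


def curve_registry():
    """Table of supported families: name -> (parameter names, count, bounds)."""
    return {
        name: {
            "param_names": spec.param_names,
            "n_params": spec.n_params,
            "default_bounds": spec.default_bounds,
        }
        for name, spec in FAMILIES.items()
    }
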