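"""Nonlinear least-squares fitting of viability-decay curves.

The objective is ordinary least squares on replicate-level viability
fractions: ``min_theta sum_i (V_i - v(t_i; theta))^2`` over all replicate
observations (so n = timepoints x replicates, e.g. 15 for the standard
5 x 3 design).  A fit over per-timepoint mean viabilities is available as a
sensitivity option, as is inverse-variance (binomial) weighting; both are
off by default.

The three-parameter Weibull objective is famously ridge-shaped: very
different (lambda, k, c) triples produce nearly identical curves when the
scale and shape grow together with an offsetting negative location.  The
fitter therefore uses a deterministic multistart enumeration, reports the
best solution found, and raises a ``condition_flag`` instead of
re-parameterising when individual parameters are ill-determined - the
fitted curve and its L50 remain well-determined on the ridge even when the
parameter triple is not.

Model ranking uses RSS-based information criteria:
``AIC = n ln(RSS/n) + 2p`` and ``BIC = n ln(RSS/n) + p ln n``,
without a variance-parameter term in ``p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .assay import ViabilityAssay
from .decay import FAMILIES, DecayParams, l50_closed_form, viability
from .errors import (
    DataError,
    DegenerateAssayError,
    FitError,
    PerfectFitError,
)

__all__ = [
    "FitOptions",
    "DecayFit",
    "DecayCurveFitter",
    "fit_decay",
    "information_criteria",
    "compare_models",
]

_LN2 = math.log(2.0)
_K_STARTS = (0.5, 1.0, 2.0, 5.0, 20.0, 100.0, 300.0)


def information_criteria(rss: float, n: int, p: int):
    """RSS-based (AIC, BIC) under the least-squares Gaussian profile.

    ``AIC = n ln(RSS/n) + 2p``; ``BIC = n ln(RSS/n) + p ln n``.  The
    parameter count ``p`` excludes the residual variance.
    """
    if rss == 0:
        raise PerfectFitError(
            "RSS is exactly zero; report a perfect fit instead of AIC/BIC"
        )
    if rss < 0:
        raise DataError(f"RSS must be positive, got {rss}")
    if p < 0 or n <= p:
        raise DataError(f"need residual count n > p >= 0, got n={n}, p={p}")
    base = n * math.log(rss / n)
    return base + 2 * p, base + p * math.log(n)


@dataclass
class FitOptions:
    """Tuning knobs for :func:`fit_decay`.

    Attributes
    ----------
    n_jitter_starts : int
        Extra multiplicatively jittered starts beyond the deterministic
        enumeration (seeded; 0 keeps the fit fully deterministic).
    rng_seed : int
        Seed for jittered starts.
    include_nested_start : bool
        For ``weibull3``, also fit the nested two-parameter model and seed
        the three-parameter search with its solution, guaranteeing
        RSS(weibull3) <= RSS(weibull2) on the same data.
    on_means : bool
        Fit per-timepoint mean viabilities instead of replicate values.
    weighted : bool
        Inverse-binomial-variance weighting of residuals.
    bounds : dict or None
        Per-parameter (lower, upper) overrides keyed by parameter name.
    condition_threshold : float
        Relative parameter uncertainty above which ``condition_flag`` is set.
    """

    n_jitter_starts: int = 0
    rng_seed: int = 0
    include_nested_start: bool = True
    on_means: bool = False
    weighted: bool = False
    bounds: Optional[dict] = None
    condition_threshold: float = 1e3
    max_nfev: Optional[int] = None


@dataclass
class DecayFit:
    """Result of fitting one decay family to one assay."""

    params: DecayParams
    rss: float
    n_obs: int
    aic: float
    bic: float
    converged: bool
    condition_flag: bool
    perfect_fit: bool = False
    lot_id: Optional[str] = None

    @property
    def family(self) -> str:
        return self.params.family

    @property
    def n_params(self) -> int:
        return self.params.n_params

    def predicted(self, t):
        """Fitted viability curve evaluated at time(s) ``t`` (days)."""
        return viability(t, self.params)

    def l50(self):
        """(L50 days, estimable flag) of the fitted curve."""
        return l50_closed_form(self.params)

    def to_dict(self) -> dict:
        l50, estimable = self.l50()
        return {
            "lot_id": self.lot_id,
            "family": self.family,
            "params": self.params.as_dict(),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "bic": self.bic,
            "l50_days": l50,
            "l50_estimable": estimable,
            "converged": self.converged,
            "condition_flag": self.condition_flag,
            "perfect_fit": self.perfect_fit,
        }


# ---------------------------------------------------------------------------
# residuals and jacobians


def _model_and_jac(family: str):
    spec = FAMILIES[family]

    if family in ("weibull3", "weibull2"):

        def model(t, theta):
            return spec.evaluate(t, theta)

        def jac(t, theta):
            if family == "weibull3":
                lam, k, c = theta
            else:
                lam, k = theta
                c = 0.0
            z = np.maximum(t - c, 0.0) / lam
            pos = z > 0
            v = np.ones_like(z)
            w = np.zeros_like(z)
            logz = np.zeros_like(z)
            logz[pos] = np.log(z[pos])
            w[pos] = np.exp(np.clip(k * logz[pos], -700, 700))
            v = np.exp(-np.clip(w, 0.0, 700.0))
            J = np.zeros((len(z), len(theta)))
            vw = v * w
            J[:, 0] = vw * k / lam
            J[:, 1] = -vw * logz
            if family == "weibull3":
                with np.errstate(divide="ignore", invalid="ignore"):
                    dc = np.where(pos, vw * k / np.maximum(t - c, 1e-300), 0.0)
                J[:, 2] = dc
            return J

    elif family == "logistic":

        def model(t, theta):
            return spec.evaluate(t, theta)

        def jac(t, theta):
            A, m, r = theta
            E = np.exp(np.clip(r * (t - m), -700, 700))
            denom = (1.0 + E) ** 2
            J = np.empty((len(t), 3))
            J[:, 0] = 1.0 / (1.0 + E)
            J[:, 1] = A * r * E / denom
            J[:, 2] = -A * (t - m) * E / denom
            return J

    else:  # gompertz

        def model(t, theta):
            return spec.evaluate(t, theta)

        def jac(t, theta):
            A, b, g = theta
            egt = np.exp(np.clip(g * t, -700, 700))
            v = A * np.exp(-np.clip(b * egt, 0.0, 700.0))
            J = np.empty((len(t), 3))
            J[:, 0] = v / A
            J[:, 1] = -v * egt
            J[:, 2] = -v * b * t * egt
            return J

    return model, jac


def _family_bounds(family: str, t_min: float, overrides=None):
    spec = FAMILIES[family]
    lo, hi = [], []
    for name, (bl, bh) in zip(spec.param_names, spec.default_bounds):
        if overrides and name in overrides:
            bl, bh = overrides[name]
        if family == "weibull3" and name == "c":
            bh = min(bh, t_min)
        lo.append(bl)
        hi.append(bh)
    return np.array(lo), np.array(hi)


def _crossing_time(t_unique, v_mean) -> float:
    """Time where linearly interpolated mean viability crosses 0.5."""
    for i in range(len(t_unique) - 1):
        a, b = v_mean[i], v_mean[i + 1]
        if (a - 0.5) * (b - 0.5) <= 0 and a != b:
            return float(
                t_unique[i] + (a - 0.5) / (a - b) * (t_unique[i + 1] - t_unique[i])
            )
    return float(np.median(t_unique))


def _starts(family: str, t_unique, v_mean, rng=None, n_jitter=0):
    m = _crossing_time(t_unique, v_mean)
    v0 = float(np.clip(v_mean[0], 1e-3, 1.0))
    starts = []
    if family in ("weibull3", "weibull2"):
        lam_set = (m + 0.5, 2 * m + 1.0, 10.0 * (m + 1.0))
        for k0 in _K_STARTS:
            for lam0 in lam_set:
                if family == "weibull3":
                    c0 = m - lam0 * _LN2 ** (1.0 / k0)
                    starts.append([lam0, k0, c0])
                else:
                    starts.append([m / _LN2 ** (1.0 / k0), k0])
    elif family == "logistic":
        for A0 in (min(1.0, max(v0, 0.55)), 1.0):
            for r0 in (0.5, 2.0, 8.0):
                starts.append([A0, m, r0])
    else:  # gompertz
        for A0 in (min(1.0, max(v0, 0.55)), 1.0):
            # displacement matching v(0): v0 = A0 * exp(-b0)
            b0 = math.log(A0 / v0) if v0 < A0 else 1e-2
            b0 = max(b0, 1e-3)
            for g0 in (0.5, 2.0, 8.0):
                starts.append([A0, b0, g0])
                starts.append([A0, 0.1, g0])
    if n_jitter and rng is not None:
        base = list(starts)
        for _ in range(n_jitter):
            s = base[rng.integers(len(base))]
            starts.append([x * float(rng.uniform(0.5, 2.0)) for x in s])
    return starts


def _clip_start(x0, lo, hi):
    pad = 1e-9 * np.maximum(1.0, np.abs(hi))
    return np.minimum(np.maximum(np.asarray(x0, dtype=float), lo + pad), hi - pad)


def _optimize(t, v, family, starts, lo, hi, weights=None, max_nfev=None):
    """Run least-squares from each start; return (best_theta, best_cost, any_success, jac_at_best)."""
    model, jac = _model_and_jac(family)
    sw = None if weights is None else np.sqrt(weights)

    def resid(theta):
        r = model(t, theta) - v
        return r if sw is None else sw * r

    def jacf(theta):
        J = jac(t, theta)
        return J if sw is None else sw[:, None] * J

    best = None
    any_success = False
    for x0 in starts:
        x0c = _clip_start(x0, lo, hi)
        try:
            res = least_squares(
                resid, x0c, jac=jacf, bounds=(lo, hi), method="trf", max_nfev=max_nfev
            )
        except Exception:
            continue
        any_success = any_success or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"no {family} start converged")
    return best, any_success


def _condition_flag(res, n_obs, n_params, threshold) -> bool:
    """Ill-conditioning diagnostic for the fitted parameter vector.

    Flags when the relative parameter uncertainty (Gauss-Newton covariance)
    exceeds ``threshold``, or when the relatively-scaled Jacobian is
    near-singular - the structural signature of the scale/shape/location
    ridge, which persists even on noise-free data where the covariance
    collapses to zero.
    """
    if n_obs <= n_params:
        return True
    scaled = res.jac * np.maximum(np.abs(res.x), 1e-12)
    if np.linalg.cond(scaled) > 3e5:
        return True
    rss = 2.0 * res.cost
    s2 = rss / (n_obs - n_params)
    JTJ = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(JTJ) * s2
    except np.linalg.LinAlgError:
        return True
    diag = np.diag(cov)
    if np.any(diag < 0) or not np.all(np.isfinite(diag)):
        return True
    rel = np.sqrt(diag) / np.maximum(np.abs(res.x), 1e-12)
    return bool(np.max(rel) > threshold)


def _fit_arrays(t, v, family, options: FitOptions, starts=None) -> DecayFit:
    """Fit one family to raw (time, viability) arrays.

    ``starts`` overrides the deterministic enumeration (used for warm-started
    bootstrap refits).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    t_unique = np.unique(t)
    v_mean = np.array([v[t == u].mean() for u in t_unique])
    if options.on_means:
        t_fit, v_fit = t_unique, v_mean
    else:
        t_fit, v_fit = t, v

    lo, hi = _family_bounds(family, float(t_fit.min()), options.bounds)

    weights = None
    if options.weighted:
        var = np.interp(t_fit, t_unique, v_mean * (1 - v_mean))
        weights = 1.0 / np.maximum(var, 1e-4)

    if starts is None:
        rng = np.random.default_rng(options.rng_seed)
        starts = _starts(family, t_unique, v_mean, rng, options.n_jitter_starts)
        if family == "weibull3" and options.include_nested_start:
            nested = _fit_arrays(
                t, v, "weibull2", replace(options, include_nested_start=False)
            )
            lam2, k2 = nested.params.values
            # the two-parameter solution lives on the c = 0 boundary
            starts = list(starts) + [[lam2, k2, min(0.0, hi[2])]]

    res, success = _optimize(
        t_fit, v_fit, family, starts, lo, hi, weights, options.max_nfev
    )
    theta = tuple(float(x) for x in res.x)
    params = DecayParams(family, theta)
    # RSS is always reported unweighted so AIC/BIC are comparable across options
    rss = float(np.sum((viability(t_fit, params) - v_fit) ** 2))
    n_obs = len(t_fit)
    if rss == 0.0:
        aic = bic = -math.inf
        perfect = True
    else:
        aic, bic = information_criteria(rss, n_obs, params.n_params)
        perfect = False
    cond = _condition_flag(res, n_obs, params.n_params, options.condition_threshold)
    return DecayFit(
        params=params,
        rss=rss,
        n_obs=n_obs,
        aic=aic,
        bic=bic,
        converged=bool(success),
        condition_flag=cond,
        perfect_fit=perfect,
    )


def _validate_assay_for_fit(assay: ViabilityAssay, n_params: int):
    if assay.n_timepoints < 3:
        raise DegenerateAssayError(
            f"assay {assay.lot_id!r} has {assay.n_timepoints} distinct times; need >= 3"
        )
    v = assay.viabilities
    if np.allclose(v, v[0]):
        raise DegenerateAssayError(
            f"degenerate assay {assay.lot_id!r}: all observations identical"
        )
    if len(v) < n_params + 1:
        raise DegenerateAssayError(
            f"assay {assay.lot_id!r} has {len(v)} observations; need > {n_params}"
        )


class DecayCurveFitter(RegressorMixin, BaseEstimator):
    """Scikit-learn style regressor for viability-decay curves.

    ``fit(X, y)`` takes aging times in days (``X``, shape ``(n,)`` or
    ``(n, 1)``) and replicate viability fractions (``y`` in [0, 1]) and
    minimises the unweighted sum of squared residuals by deterministic
    multistart nonlinear least squares.  ``predict(X)`` evaluates the fitted
    curve.  Composes with sklearn model selection; ``score`` is the usual
    R^2.

    Parameters
    ----------
    family : str, default "weibull3"
        Curve family (``weibull3``, ``weibull2``, ``logistic``,
        ``gompertz``).
    n_jitter_starts : int, default 0
        Extra seeded random starts beyond the deterministic enumeration.
    random_state : int, default 0
        Seed for jittered starts.
    include_nested_start : bool, default True
        Seed the weibull3 search with the fitted weibull2 solution.
    on_means, weighted : bool
        Sensitivity options, see :class:`FitOptions`.

    Attributes
    ----------
    params_ : DecayParams
    rss_, aic_, bic_ : float
    l50_ : float and ``l50_estimable_`` : bool
    converged_, condition_flag_ : bool
    result_ : DecayFit
    """

    def __init__(
        self,
        family: str = "weibull3",
        n_jitter_starts: int = 0,
        random_state: int = 0,
        include_nested_start: bool = True,
        on_means: bool = False,
        weighted: bool = False,
        bounds: Optional[dict] = None,
    ):
        self.family = family
        self.n_jitter_starts = n_jitter_starts
        self.random_state = random_state
        self.include_nested_start = include_nested_start
        self.on_means = on_means
        self.weighted = weighted
        self.bounds = bounds

    def _options(self) -> FitOptions:
        return FitOptions(
            n_jitter_starts=self.n_jitter_starts,
            rng_seed=self.random_state,
            include_nested_start=self.include_nested_start,
            on_means=self.on_means,
            weighted=self.weighted,
            bounds=self.bounds,
        )

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t.ravel()
        if t.ndim != 1:
            raise DataError("X must be 1-d times or an (n, 1) column")
        v = np.asarray(y, dtype=float)
        if v.shape != t.shape:
            raise DataError("X and y lengths differ")
        if np.any(t < 0):
            raise DataError("aging times must be >= 0")
        if np.any((v < 0) | (v > 1)):
            raise DataError("viability values must lie in [0, 1]")
        if self.family not in FAMILIES:
            raise DataError(f"unknown family {self.family!r}")
        if len(np.unique(t)) < 3:
            raise DegenerateAssayError("need >= 3 distinct times")
        if np.allclose(v, v[0]):
            raise DegenerateAssayError("degenerate assay: all observations identical")
        fit = _fit_arrays(t, v, self.family, self._options())
        self.result_ = fit
        self.params_ = fit.params
        self.rss_ = fit.rss
        self.n_obs_ = fit.n_obs
        self.aic_ = fit.aic
        self.bic_ = fit.bic
        self.converged_ = fit.converged
        self.condition_flag_ = fit.condition_flag
        self.l50_, self.l50_estimable_ = fit.l50()
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t.ravel()
        return np.asarray(viability(t, self.params_), dtype=float)

    def fit_assay(self, assay: ViabilityAssay):
        """Fit from a :class:`ViabilityAssay` instead of raw arrays."""
        _validate_assay_for_fit(assay, FAMILIES[self.family].n_params)
        self.fit(assay.times, assay.viabilities)
        self.result_.lot_id = assay.lot_id
        return self


def fit_decay(
    assay: ViabilityAssay, family: str = "weibull3", options: Optional[FitOptions] = None
) -> DecayFit:
    """Fit one decay family to a replicate-level assay by multistart NLS.

    Parameters
    ----------
    assay : ViabilityAssay
        Replicate-level observations; needs >= 3 distinct times and some
        variation in viability.
    family : str
        One of the registered curve families.
    options : FitOptions, optional
        Multistart, weighting and bound controls.

    Returns
    -------
    DecayFit
        Best solution over all starts, with RSS-based AIC/BIC and an
        ill-conditioning flag.
    """
    if family not in FAMILIES:
        raise DataError(f"unknown family {family!r}")
    options = options or FitOptions()
    _validate_assay_for_fit(assay, FAMILIES[family].n_params)
    fit = _fit_arrays(assay.times, assay.viabilities, family, options)
    fit.lot_id = assay.lot_id
    return fit


def compare_models(
    assay: ViabilityAssay,
    families=("weibull3", "weibull2", "logistic", "gompertz"),
    options: Optional[FitOptions] = None,
):
    """Fit several families to one assay and rank them by AIC.

    Returns a pandas DataFrame with one row per family (params, rss, aic,
    bic, delta_aic), sorted ascending by AIC with ties broken by fewer
    parameters then family name.  Per-family fit failures become flagged
    rows rather than exceptions.
    """
    import pandas as pd

    families = list(families)
    if len(families) < 2:
        raise DataError("need >= 2 families to compare")
    rows = []
    fits = {}
    for fam in families:
        try:
            fit = fit_decay(assay, fam, options)
        except (DegenerateAssayError, FitError, DataError) as exc:
            rows.append(
                {
                    "family": fam,
                    "n_params": FAMILIES[fam].n_params if fam in FAMILIES else None,
                    "params": None,
                    "rss": np.nan,
                    "aic": np.nan,
                    "bic": np.nan,
                    "l50_days": np.nan,
                    "error": str(exc),
                }
            )
            continue
        fits[fam] = fit
        l50, _ = fit.l50()
        rows.append(
            {
                "family": fam,
                "n_params": fit.n_params,
                "params": fit.params.as_dict(),
                "rss": fit.rss,
                "aic": fit.aic,
                "bic": fit.bic,
                "l50_days": l50,
                "error": "",
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["aic", "n_params", "family"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    finite = df["aic"].notna()
    best = df.loc[finite, "aic"].min() if finite.any() else np.nan
    df["delta_aic"] = df["aic"] - best
    df.attrs["fits"] = fits
    return df
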