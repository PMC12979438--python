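"""From fitted decay curves to longevity estimates.

This module turns per-lot L50 values (median-viability times under
accelerated aging) into an age-resolved longevity model:

1. ``l50_with_ci`` - point estimate plus a case-resampling bootstrap
   percentile interval for one assay.
2. ``L50AgeRegression`` - regression of L50 on chronological seed age,
   either a second-order polynomial (the headline form) or a 4-parameter
   Weibull-shaped curve ``y = A * exp(-((x + B) / C) ** D)``.
3. ``longevity_bound`` - the ages at which the quadratic predicts L50 = 0;
   the smaller positive root is the extrapolated upper bound of seed
   longevity (the larger root is reported but discarded on germination
   evidence: seeds older than the smaller root no longer germinate).
4. ``equivalent_age`` - inverse mapping from an observed L50 (e.g. a
   soil-seed-bank lot) to the storage age with the same expected L50.
5. Validation statistics: one-way ANOVA on replicate-level L50 values and
   germination-trial summaries with Tukey-HSD letter groupings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .assay import ViabilityAssay

from .errors import DataError, FitError
from .fitting import FitOptions, _fit_arrays, fit_decay, information_criteria

__all__ = [
    "L50Estimate",
    "AgeL50Point",
    "L50AgeRegression",
    "LongevityBound",
    "GerminationTrial",
    "l50_with_ci",
    "l50_age_regression",
    "evaluate_regression",
    "longevity_bound",
    "equivalent_age",
    "anova_oneway",
    "germination_summary",
]


# ---------------------------------------------------------------------------
# L50 with bootstrap interval


@dataclass
class L50Estimate:
    """Median-viability time for one lot with a bootstrap percentile interval."""

    l50: float
    estimable: bool
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    b_boot: int = 0
    rng_seed: int = 0
    lot_id: Optional[str] = None
    warning: str = ""

    def to_dict(self) -> dict:
        return {
            "lot_id": self.lot_id,
            "l50_days": self.l50,
            "estimable": self.estimable,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "b_boot": self.b_boot,
            "rng_seed": self.rng_seed,
            "warning": self.warning,
        }


def l50_with_ci(
    assay: ViabilityAssay,
    family: str = "weibull3",
    b_boot: int = 1000,
    rng_seed: int = 0,
    options: Optional[FitOptions] = None,
    ci_level: float = 0.95,
    method: str = "parametric",
) -> L50Estimate:
    """L50 point estimate with a seeded bootstrap percentile interval.

    The point estimate is the closed-form L50 of the full-data fit.  Each
    bootstrap replicate builds a pseudo-dataset, refits the curve
    (warm-started from the full-data solution) and records the resulting
    L50; resamples whose curve is already below 50% viability at t = 0
    contribute 0, matching the clamping convention for collapsed lots.  The
    interval is the 2.5/97.5 percentile range (for the default 95% level).

    ``method="parametric"`` (default) redraws each replicate's viable count
    as Binomial(n_tested, v_hat(t)) from the fitted curve - with 3
    replicates per timepoint this tracks the nominal level closely.
    ``method="case"`` resamples replicates with replacement within each
    timepoint; with very few replicates per timepoint it systematically
    understates the sampling variance and under-covers, so it is offered
    only for sensitivity analysis.

    With fewer than 2 replicates per timepoint the interval is withheld and
    only the point estimate returned, with a warning flag.
    """
    if method not in ("parametric", "case"):
        raise DataError(f"unknown bootstrap method {method!r}")
    options = options or FitOptions()
    fit = fit_decay(assay, family, options)
    l50, estimable = fit.l50()

    t = assay.times
    v = assay.viabilities
    n_tested = np.array([o.n_tested for o in assay.observations], dtype=int)
    t_unique = np.unique(t)
    groups = [np.where(t == u)[0] for u in t_unique]
    if min(len(g) for g in groups) < 2:
        return L50Estimate(
            l50=l50,
            estimable=estimable,
            b_boot=0,
            rng_seed=rng_seed,
            lot_id=assay.lot_id,
            warning="fewer than 2 replicates per timepoint; interval unavailable",
        )

    rng = np.random.default_rng(rng_seed)
    warm = list(fit.params.values)
    boot_opts = FitOptions(
        include_nested_start=False,
        on_means=options.on_means,
        weighted=options.weighted,
        bounds=options.bounds,
    )
    v_hat = fit.predicted(t)
    draws = np.empty(b_boot)
    for b in range(b_boot):
        if method == "parametric":
            tb = t
            vb = rng.binomial(n_tested, v_hat) / n_tested
        else:
            idx = np.concatenate(
                [rng.choice(g, size=len(g), replace=True) for g in groups]
            )
            tb, vb = t[idx], v[idx]
        try:
            refit = _fit_arrays(tb, vb, family, boot_opts, starts=[warm])
            lb, ok = refit.l50()
        except (FitError, ValueError):
            lb, ok = l50, estimable
        draws[b] = lb if ok else 0.0
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return L50Estimate(
        l50=l50,
        estimable=estimable,
        ci_low=float(lo),
        ci_high=float(hi),
        b_boot=b_boot,
        rng_seed=rng_seed,
        lot_id=assay.lot_id,
    )


# ---------------------------------------------------------------------------
# L50 ~ age regression


@dataclass(frozen=True)
class AgeL50Point:
    """One (seed age in years, L50 in days) pair."""

    age: float
    l50: float

    def __post_init__(self):
        if self.age < 0:
            raise DataError(f"age must be >= 0, got {self.age}")
        if self.l50 < 0:
            raise DataError(f"L50 must be >= 0, got {self.l50}")


@dataclass
class LongevityBound:
    """Roots of the quadratic L50-age curve and the designated bound.

    ``root_small`` (years) is the headline longevity upper bound; the larger
    root is also reported, with the convention that germination evidence on
    old seed lots decides between them.
    """

    root_small: Optional[float]
    root_large: Optional[float]
    crossing: bool
    bound: Optional[float]

    def to_dict(self) -> dict:
        return {
            "root_small_years": self.root_small,
            "root_large_years": self.root_large,
            "crossing": self.crossing,
            "longevity_bound_years": self.bound,
        }


_W4_BOUNDS = (
    np.array([1e-6, 1e-6, 1e-3, 1e-2]),
    np.array([1e4, 1e3, 1e4, 1e3]),
)


def _w4_curve(x, theta):
    A, B, C, D = theta
    z = np.maximum(x + B, 1e-12) / C
    return A * np.exp(-np.clip(z**D, 0.0, 700.0))


class L50AgeRegression(RegressorMixin, BaseEstimator):
    """Regression of L50 (days) on seed age (years).

    ``form="quadratic"`` fits ``y = b0 + b1 x + b2 x^2`` by exact least
    squares; ``form="weibull4"`` fits ``y = A exp(-((x + B)/C)^D)`` by
    deterministic multistart nonlinear least squares.  Both report RSS, the
    plain coefficient of determination R^2, and RSS-based AIC/BIC with
    p = 3 or 4 parameters.

    Attributes
    ----------
    coef_ : ndarray
        ``[intercept, b1, b2]`` or ``[A, B, C, D]``.
    stderr_ : ndarray or None
        Coefficient standard errors (quadratic only).
    rss_, r_squared_, aic_, bic_ : float
    n_points_ : int
    """

    _MIN_POINTS = {"quadratic": 4, "weibull4": 5}
    _N_PARAMS = {"quadratic": 3, "weibull4": 4}

    def __init__(self, form: str = "quadratic"):
        self.form = form

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y):
        if self.form not in self._MIN_POINTS:
            raise DataError(f"unknown regression form {self.form!r}")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x.ravel()
        yv = np.asarray(y, dtype=float)
        if x.shape != yv.shape or x.ndim != 1:
            raise DataError("X and y must be matching 1-d arrays")
        n_min = self._MIN_POINTS[self.form]
        if len(x) < n_min:
            raise DataError(
                f"{self.form} regression needs >= {n_min} points, got {len(x)}"
            )
        if self.form == "quadratic":
            self._fit_quadratic(x, yv)
        else:
            self._fit_weibull4(x, yv)
        self.n_points_ = len(x)
        self.rss_, self.r_squared_, self.aic_, self.bic_ = _regression_metrics(
            yv, self.predict(x), self._N_PARAMS[self.form]
        )
        return self

    def _fit_quadratic(self, x, y):
        V = np.vander(x, 3, increasing=True)
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
        resid = y - V @ coef
        dof = len(x) - 3
        s2 = float(resid @ resid) / dof if dof > 0 else np.nan
        cov = s2 * np.linalg.inv(V.T @ V)
        self.coef_ = coef
        self.stderr_ = np.sqrt(np.diag(cov))

    def _fit_weibull4(self, x, y):
        ymax = float(np.max(y))
        ypos = max(float(np.min(y[y > 0], initial=ymax)), 1e-6)
        best = None
        from scipy.optimize import least_squares

        lo, hi = _W4_BOUNDS
        for A0 in (max(ymax, 1e-3) * f for f in (1.05, 2.0, 6.0)):
            for D0 in (1.0, 2.0, 3.0):
                for B0 in (1.0, 10.0, 25.0):
                    # choose C0 so the curve passes near (0, y[argmin x])
                    y0 = float(np.clip(y[np.argmin(x)], ypos, A0 * (1 - 1e-9)))
                    C0 = B0 / max(math.log(A0 / y0), 1e-9) ** (1.0 / D0)
                    x0 = np.clip([A0, B0, C0, D0], lo + 1e-9, hi - 1e-9)
                    try:
                        res = least_squares(
                            lambda th: _w4_curve(x, th) - y, x0, bounds=(lo, hi)
                        )
                    except Exception:
                        continue
                    if best is None or res.cost < best.cost:
                        best = res
        if best is None:
            raise FitError("no weibull4 start converged")
        self.coef_ = best.x.copy()
        self.stderr_ = None

    @classmethod
    def from_coefficients(cls, form: str, coef: Sequence[float]) -> "L50AgeRegression":
        """Build a regression object from externally supplied coefficients."""
        reg = cls(form=form)
        coef = np.asarray(coef, dtype=float)
        if len(coef) != reg._N_PARAMS.get(form, -1):
            raise DataError(
                f"{form} takes {reg._N_PARAMS.get(form)} coefficients, got {len(coef)}"
            )
        reg.coef_ = coef
        reg.stderr_ = None
        return reg

    # -- evaluation --------------------------------------------------------

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x.ravel()
        if self.form == "quadratic":
            b0, b1, b2 = self.coef_
            return b0 + b1 * x + b2 * x**2
        return _w4_curve(x, self.coef_)

    def score_points(self, X, y):
        """(rss, r_squared, aic, bic) of this fixed curve on given points, no refit."""
        yv = np.asarray(y, dtype=float)
        return _regression_metrics(yv, self.predict(X), self._N_PARAMS[self.form])

    # -- quadratic-specific closed forms -----------------------------------

    def longevity_bound(self) -> LongevityBound:
        """Ages (years) at which the quadratic predicts L50 = 0."""
        check_is_fitted(self, "coef_")
        if self.form != "quadratic":
            raise DataError("longevity_bound requires the quadratic form")
        b0, b1, b2 = self.coef_
        if b0 == 0 and b1 == 0 and b2 == 0:
            raise DataError("degenerate all-zero quadratic")
        if b2 == 0:
            if b1 == 0:
                return LongevityBound(None, None, False, None)
            root = -b0 / b1
            return LongevityBound(root, None, True, root if root > 0 else None)
        disc = b1 * b1 - 4 * b2 * b0
        if disc < 0:
            return LongevityBound(None, None, False, None)
        sq = math.sqrt(disc)
        r1 = (-b1 - sq) / (2 * b2)
        r2 = (-b1 + sq) / (2 * b2)
        small, large = sorted((r1, r2))
        positive = [r for r in (small, large) if r > 0]
        bound = positive[0] if positive else None
        return LongevityBound(small, large, True, bound)

    def equivalent_age(self, l50: float) -> float:
        """Age (years) whose expected L50 equals the given value (quadratic only).

        Returns the smaller root of ``quadratic(x) = l50`` on
        ``[0, root_small]`` - the storage age with the same expected decay
        resistance as the observed lot.
        """
        check_is_fitted(self, "coef_")
        if self.form != "quadratic":
            raise DataError("equivalent_age requires the quadratic form")
        b0, b1, b2 = self.coef_
        if b0 < l50 <= b0 + 1e-6 * max(1.0, abs(b0)):
            l50 = b0  # within rounding of the age-0 reference
        if not (0 < l50 <= b0):
            raise DataError(
                f"L50 {l50} is fresher than the age-0 reference (intercept {b0:.4f})"
                if l50 > b0
                else f"L50 must be positive, got {l50}"
            )
        disc = b1 * b1 - 4 * b2 * (b0 - l50)
        if b2 == 0:
            return (l50 - b0) / b1
        if disc < 0:
            raise DataError("quadratic never attains the requested L50")
        sq = math.sqrt(disc)
        roots = sorted(((-b1 - sq) / (2 * b2), (-b1 + sq) / (2 * b2)))
        for r in roots:
            if r >= -1e-12:
                return max(r, 0.0)
        raise DataError("no non-negative age maps to the requested L50")

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        names = (
            ("intercept", "b1", "b2") if self.form == "quadratic" else ("A", "B", "C", "D")
        )
        out = {
            "form": self.form,
            "coefficients": dict(zip(names, (float(c) for c in self.coef_))),
        }
        for attr in ("rss_", "r_squared_", "aic_", "bic_", "n_points_"):
            if hasattr(self, attr):
                out[attr.rstrip("_")] = getattr(self, attr)
        if getattr(self, "stderr_", None) is not None:
            out["stderr"] = dict(zip(names, (float(s) for s in self.stderr_)))
        return out


def _regression_metrics(y, yhat, p):
    resid = y - yhat
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    n = len(y)
    if rss == 0:
        return rss, r2, -math.inf, -math.inf
    aic, bic = information_criteria(rss, n, p)
    return rss, r2, aic, bic


def _points_to_arrays(points):
    if isinstance(points, pd.DataFrame):
        return points["age_years"].to_numpy(float), points["l50_days"].to_numpy(float)
    pts = [(p.age, p.l50) if isinstance(p, AgeL50Point) else (p[0], p[1]) for p in points]
    arr = np.asarray(pts, dtype=float)
    return arr[:, 0], arr[:, 1]


def l50_age_regression(points, form: str = "quadratic") -> L50AgeRegression:
    """Fit the L50-vs-age regression to (age, L50) points.

    ``points`` may be an iterable of :class:`AgeL50Point`, of ``(age, l50)``
    pairs, or a DataFrame with ``age_years``/``l50_days`` columns.
    """
    x, y = _points_to_arrays(points)
    return L50AgeRegression(form=form).fit(x, y)


def evaluate_regression(reg: L50AgeRegression, points):
    """Residual metrics (rss, r_squared, aic, bic) of a fixed curve on points."""
    x, y = _points_to_arrays(points)
    return reg.score_points(x, y)


def longevity_bound(reg: L50AgeRegression) -> LongevityBound:
    """Roots of the fitted quadratic; the smaller positive root is the bound."""
    return reg.longevity_bound()


def equivalent_age(reg: L50AgeRegression, l50: float) -> float:
    """Storage age (years) with the same expected L50 as the observed lot."""
    return reg.equivalent_age(l50)


# ---------------------------------------------------------------------------
# validation statistics


def anova_oneway(groups: Sequence[Sequence[float]]):
    """Classical one-way fixed-effects ANOVA from the definitional sums of squares.

    Parameters
    ----------
    groups : sequence of sequences
        >= 2 groups of replicate-level values (e.g. per-replicate L50s per
        population), each with >= 2 values.

    Returns
    -------
    dict with F, df_between, df_within, p, ss_between, ss_within, ss_total,
    and ``undefined`` (True when both variance components vanish).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise DataError("need >= 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise DataError("each group needs >= 2 values")
    all_vals = np.concatenate(arrays)
    n_total = len(all_vals)
    k = len(arrays)
    if n_total <= k:
        raise DataError("total observations must exceed the group count")
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_total = ((all_vals - grand) ** 2).sum()
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0 and ss_between == 0:
        return {
            "F": np.nan,
            "df_between": df_b,
            "df_within": df_w,
            "p": np.nan,
            "ss_between": 0.0,
            "ss_within": 0.0,
            "ss_total": float(ss_total),
            "undefined": True,
        }
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = np.inf if ms_w == 0 else ms_b / ms_w
    p = 0.0 if not np.isfinite(F) else float(stats.f.sf(F, df_b, df_w))
    return {
        "F": float(F),
        "df_between": df_b,
        "df_within": df_w,
        "p": p,
        "ss_between": float(ss_between),
        "ss_within": float(ss_within),
        "ss_total": float(ss_total),
        "undefined": False,
    }


@dataclass
class GerminationTrial:
    """Replicate germination percentages for one cohort."""

    cohort: str
    replicate_percentages: list
    letter: str = ""

    def __post_init__(self):
        vals = [float(v) for v in self.replicate_percentages]
        if len(vals) < 2:
            raise DataError(f"cohort {self.cohort!r} needs >= 2 replicates")
        if any(not (0 <= v <= 100) for v in vals):
            raise DataError(f"cohort {self.cohort!r} has percentages outside [0, 100]")
        self.replicate_percentages = vals

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_percentages))

    @property
    def sd(self) -> float:
        """Sample standard deviation (n - 1 denominator)."""
        return float(np.std(self.replicate_percentages, ddof=1))

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "n": len(self.replicate_percentages),
            "mean": self.mean,
            "sd": self.sd,
            "letter": self.letter,
            "replicates": self.replicate_percentages,
        }


def _compact_letters(names, means, different) -> dict:
    """Compact letter display: groups sharing a letter are not significantly different.

    ``different[i][j]`` is True when groups i and j differ at the chosen
    alpha.  Basic insert-and-absorb construction over groups in ascending
    mean order ('a' marks the lowest-mean class).
    """
    order = sorted(range(len(names)), key=lambda i: means[i])
    classes = []  # each class: set of group indices sharing one letter
    for i in order:
        placed = False
        for cls in classes:
            if all(not different[i][j] for j in cls):
                cls.add(i)
                placed = True
        if not placed:
            classes.append({i})
    # absorb classes fully contained in another
    classes = [
        c
        for idx, c in enumerate(classes)
        if not any(idx != jdx and c < other for jdx, other in enumerate(classes))
    ]
    letters = {i: "" for i in range(len(names))}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for i in cls:
            letters[i] += letter
    return {names[i]: "".join(sorted(letters[i])) for i in range(len(names))}


def germination_summary(trials, alpha: float = 0.05) -> list:
    """Summarise germination trials: mean, sample SD and Tukey-HSD letters.

    Parameters
    ----------
    trials : mapping cohort -> replicate percentages, or list of
        :class:`GerminationTrial`.
    alpha : float
        Significance level for Tukey's HSD grouping.

    Returns
    -------
    list of GerminationTrial with the ``letter`` field filled in (cohorts
    sharing a letter do not differ significantly).
    """
    if isinstance(trials, dict):
        trials = [GerminationTrial(str(k), list(v)) for k, v in trials.items()]
    else:
        trials = list(trials)
    names = [t.cohort for t in trials]
    if len(trials) >= 2:
        values = np.concatenate([t.replicate_percentages for t in trials])
        labels = np.concatenate(
            [[t.cohort] * len(t.replicate_percentages) for t in trials]
        )
        if np.ptp(values) == 0:
            different = [[False] * len(trials) for _ in trials]
        else:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            res = pairwise_tukeyhsd(values, labels, alpha=alpha)
            different = [[False] * len(trials) for _ in trials]
            idx = {name: i for i, name in enumerate(res.groupsunique)}
            pos = {name: i for i, name in enumerate(names)}
            for (g1, g2), reject in zip(
                ((a, b) for i, a in enumerate(res.groupsunique) for b in res.groupsunique[i + 1:]),
                res.reject,
            ):
                i, j = pos[str(g1)], pos[str(g2)]
                different[i][j] = different[j][i] = bool(reject)
        letters = _compact_letters(names, [t.mean for t in trials], different)
        for t in trials:
            t.letter = letters[t.cohort]
    return trials
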