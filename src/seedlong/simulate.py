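"""Synthetic data with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration, including the
random seed, so all pipeline stages are testable without any external data:

* ``simulate_assay`` - binomial viability counts sampled along a known
  decay curve at a handful of timepoints (default: the standard design of
  5 timepoints at 0-4 days, 3 replicates of 50 seeds).
* ``simulate_cohort_series`` - a set of assays whose true L50 declines
  with seed age along a known quadratic; shape and location are held fixed
  across ages and the scale is back-solved per age, so the true L50 per
  cohort is unambiguous.
* ``simulate_germination`` - replicate germination percentages as binomial
  draws (default: 6 replicates of 30 seeds).
* ``render_seed_image`` - a stained-seed-section raster with an exactly
  known stained-pixel fraction, for validating the image-quantification
  stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .assay import ViabilityAssay, ViabilityObservation
from .decay import DecayParams, l50_closed_form, viability
from .errors import DataError

__all__ = [
    "SimulationConfig",
    "CohortSpec",
    "DEFAULT_QUADRATIC",
    "simulate_assay",
    "simulate_cohort_series",
    "simulate_germination",
    "render_seed_image",
]

_LN2 = math.log(2.0)

# Reference quadratic L50(age) law (intercept, linear, quadratic terms;
# days vs years) used as the default cohort-series truth.
DEFAULT_QUADRATIC = (2.403749, -0.403234, 0.016114)


@dataclass
class CohortSpec:
    """Age-resolved truth for a cohort series.

    The true L50 at age ``x`` follows ``q0 + q1 x + q2 x^2``; each cohort's
    decay curve shares the configured shape ``k`` and location ``c`` and
    back-solves its scale ``lambda = (L50 - c) / (ln 2)^(1/k)``.

    The default shape/location (k = 3.6, c = -0.9 days) matches the
    identifiable fits reported for old seed lots, the age range that
    dominates the extrapolation.
    """

    ages: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 8.0)
    quadratic: tuple = DEFAULT_QUADRATIC
    k: float = 3.6
    c: float = -0.9

    def true_l50(self, age: float) -> float:
        q0, q1, q2 = self.quadratic
        return q0 + q1 * age + q2 * age * age


@dataclass
class SimulationConfig:
    """Study-design parameters for the binomial assay generator."""

    params: Optional[DecayParams] = None
    timepoints: tuple = (0.0, 1.0, 2.0, 3.0, 4.0)
    replicates: int = 3
    seeds_per_replicate: int = 50
    rng_seed: int = 0
    cohort: Optional[CohortSpec] = None

    def __post_init__(self):
        if self.replicates <= 0 or self.seeds_per_replicate <= 0:
            raise DataError("replicate and seed counts must be positive")
        if len(self.timepoints) == 0:
            raise DataError("need at least one timepoint")


def simulate_assay(
    config: SimulationConfig, lot_id: str = "sim", collection_year=None
) -> ViabilityAssay:
    """Draw one binomial assay along the configured true decay curve.

    For each timepoint t and replicate, ``n_viable ~ Binomial(n_seeds,
    v(t))``.  Deterministic under a fixed ``rng_seed``.
    """
    if config.params is None:
        raise DataError("config.params must carry the true decay curve")
    rng = np.random.default_rng(config.rng_seed)
    obs = []
    for t in config.timepoints:
        p = viability(float(t), config.params)
        counts = rng.binomial(config.seeds_per_replicate, p, size=config.replicates)
        for r, n_viable in enumerate(counts, start=1):
            obs.append(
                ViabilityObservation(
                    time=float(t),
                    replicate=r,
                    n_tested=config.seeds_per_replicate,
                    n_viable=int(n_viable),
                )
            )
    return ViabilityAssay(
        lot_id=lot_id, observations=obs, collection_year=collection_year
    )


def simulate_cohort_series(config: SimulationConfig):
    """Simulate one assay per age with true L50 following the cohort quadratic.

    Returns
    -------
    list of (age_years, true_l50_days, ViabilityAssay)
        Ages in the configured grid; each assay draws fresh binomial noise
        from a seed derived deterministically from ``config.rng_seed``.

    Raises
    ------
    DataError
        If the target L50 at some age does not exceed the location ``c``
        (which would require a non-positive scale).
    """
    cohort = config.cohort or CohortSpec()
    root = np.random.default_rng(config.rng_seed)
    out = []
    for age in cohort.ages:
        l50_target = cohort.true_l50(float(age))
        if l50_target <= cohort.c:
            raise DataError(
                f"age {age}: target L50 {l50_target:.4f} d does not exceed the "
                f"location c={cohort.c}; scale would be non-positive"
            )
        lam = (l50_target - cohort.c) / _LN2 ** (1.0 / cohort.k)
        params = DecayParams("weibull3", (lam, cohort.k, cohort.c))
        sub = SimulationConfig(
            params=params,
            timepoints=config.timepoints,
            replicates=config.replicates,
            seeds_per_replicate=config.seeds_per_replicate,
            rng_seed=int(root.integers(2**31 - 1)),
        )
        assay = simulate_assay(sub, lot_id=f"age{age:g}")
        true_l50, _ = l50_closed_form(params)
        out.append((float(age), true_l50, assay))
    return out


def simulate_germination(
    n_reps: int = 6, n_seeds: int = 30, p_germ: float = 0.5, rng_seed: int = 0
) -> list:
    """Replicate germination percentages, ``100 * Binomial(n, p) / n`` each."""
    if not (0.0 <= p_germ <= 1.0):
        raise DataError(f"germination probability must be in [0, 1], got {p_germ}")
    if n_reps <= 0 or n_seeds <= 0:
        raise DataError("replicate and seed counts must be positive")
    rng = np.random.default_rng(rng_seed)
    counts = rng.binomial(n_seeds, p_germ, size=n_reps)
    return [100.0 * c / n_seeds for c in counts]


# RGB colours chosen to sit inside / outside the default red-stain windows
_RED = (200, 30, 30)  # formazan-stained tissue
_PALE = (230, 215, 140)  # unstained section tissue
_WHITE = (255, 255, 255)  # background


def render_seed_image(
    target_fraction: float,
    size: tuple = (200, 200),
    rng_seed: int = 0,
    noise: int = 0,
):
    """Render an elliptical seed "section" with a known stained fraction.

    A centred ellipse on a white background is filled with pale unstained
    tissue; a contiguous region of exactly ``round(target_fraction *
    section_pixels)`` pixels (swept column-by-column from the left) is
    painted stain-red.  Optional uniform +-``noise`` jitter per channel is
    seeded.

    Returns
    -------
    (image, truth) : (ndarray uint8 HxWx3, dict)
        ``truth`` records section_pixels, stained_pixels and the realised
        stained fraction.
    """
    if not (0.0 <= target_fraction <= 1.0):
        raise DataError(f"target fraction must be in [0, 1], got {target_fraction}")
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h * 0.38, w * 0.30
    section = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    n_section = int(section.sum())
    n_stained = int(round(target_fraction * n_section))

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = _WHITE
    img[section] = _PALE
    if n_stained > 0:
        # paint section pixels in column-major sweep: a contiguous left lobe
        cols_first = np.argwhere(section.T)  # (x, y) sorted by column
        chosen = cols_first[:n_stained]
        img[chosen[:, 1], chosen[:, 0]] = _RED
    if noise > 0:
        rng = np.random.default_rng(rng_seed)
        jitter = rng.integers(-noise, noise + 1, size=img.shape)
        img = np.clip(img.astype(int) + jitter, 0, 255).astype(np.uint8)
    truth = {
        "section_pixels": n_section,
        "stained_pixels": n_stained,
        "stained_fraction": n_stained / n_section if n_section else 0.0,
    }
    return img, truth
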