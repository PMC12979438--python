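"""Replicate-level viability assays and their CSV representation.

An accelerated-aging assay follows one seed lot: at each sampling time a
fixed number of replicates (mesh bags) of ``n_tested`` seeds each is
withdrawn and scored, giving a viable count per replicate.  The standard
design is 5 timepoints (0-4 days) x 3 replicates x 50 seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["ViabilityObservation", "ViabilityAssay", "load_viability_table"]


@dataclass(frozen=True)
class ViabilityObservation:
    """One replicate score: ``n_viable`` of ``n_tested`` seeds alive at ``time`` days.

    ``viability_override`` carries an exact fraction for records loaded from
    percentage columns, where the true seed counts are unknown.
    """

    time: float
    replicate: int
    n_tested: int
    n_viable: int
    viability_override: Optional[float] = None

    def __post_init__(self):
        if self.time < 0:
            raise DataError(f"aging time must be >= 0, got {self.time}")
        if self.n_tested <= 0:
            raise DataError(f"n_tested must be > 0, got {self.n_tested}")
        if not (0 <= self.n_viable <= self.n_tested):
            raise DataError(
                f"n_viable must lie in [0, n_tested]; got {self.n_viable}/{self.n_tested}"
            )
        if self.viability_override is not None and not (
            0.0 <= self.viability_override <= 1.0
        ):
            raise DataError(
                f"viability must lie in [0, 1], got {self.viability_override}"
            )

    @property
    def viability(self) -> float:
        """Viable fraction V in [0, 1]."""
        if self.viability_override is not None:
            return self.viability_override
        return self.n_viable / self.n_tested


@dataclass
class ViabilityAssay:
    """All replicate observations for one seed lot, sorted by (time, replicate)."""

    lot_id: str
    observations: list
    collection_year: Optional[int] = None
    habitat: Optional[str] = None
    ragged: bool = field(init=False, default=False)

    def __post_init__(self):
        if not self.observations:
            raise DataError(f"assay {self.lot_id!r} has no observations")
        self.observations = sorted(
            self.observations, key=lambda o: (o.time, o.replicate)
        )
        times = self.times
        counts = pd.Series(times).value_counts()
        # ragged designs (unequal replicate counts per timepoint) are legal
        # but flagged, because the within-timepoint bootstrap assumes balance
        self.ragged = counts.nunique() > 1

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time for o in self.observations], dtype=float)

    @property
    def viabilities(self) -> np.ndarray:
        return np.array([o.viability for o in self.observations], dtype=float)

    @property
    def n_timepoints(self) -> int:
        return len(np.unique(self.times))

    def age_years(self, reference_year: int = 2023) -> Optional[float]:
        """Seed age (years) at testing time; the test campaign fixes the reference year."""
        if self.collection_year is None:
            return None
        return float(reference_year - self.collection_year)

    def mean_by_time(self):
        """(unique times, mean viability per time) on the fraction scale."""
        t = self.times
        v = self.viabilities
        ut = np.unique(t)
        return ut, np.array([v[t == u].mean() for u in ut])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lot_id": self.lot_id,
                "collection_year": self.collection_year,
                "habitat": self.habitat,
                "time_days": [o.time for o in self.observations],
                "replicate": [o.replicate for o in self.observations],
                "n_tested": [o.n_tested for o in self.observations],
                "n_viable": [o.n_viable for o in self.observations],
            }
        )


_REQUIRED = ["lot_id", "time_days", "replicate"]


def load_viability_table(source) -> list:
    """Read a viability-assay CSV into a list of :class:`ViabilityAssay`.

    Expected columns: ``lot_id, time_days, replicate`` plus either the count
    pair ``n_tested, n_viable`` or a ``percent_viable`` column (divided by
    100 on load; count columns then default to 100 "virtual" seeds so the
    fraction round-trips exactly).  Optional metadata columns
    ``collection_year`` and ``habitat`` are carried through.

    Raises
    ------
    DataError
        On missing columns or any row violating an invariant; the message
        names the offending (1-based, header-exclusive) row number.
    """
    df = pd.read_csv(source)
    missing = [c for c in _REQUIRED if c not in df.columns]
    has_counts = {"n_tested", "n_viable"}.issubset(df.columns)
    has_percent = "percent_viable" in df.columns
    if missing or not (has_counts or has_percent):
        need = missing + ([] if has_counts or has_percent else ["n_tested/n_viable or percent_viable"])
        raise DataError(f"viability table is missing columns: {need}")

    assays = []
    for lot_id, group in df.groupby("lot_id", sort=True):
        obs = []
        for idx, row in group.iterrows():
            rowno = idx + 1
            try:
                if has_counts and not (
                    pd.isna(row.get("n_tested")) or pd.isna(row.get("n_viable"))
                ):
                    n_tested = int(row["n_tested"])
                    n_viable = int(row["n_viable"])
                else:
                    pct = float(row["percent_viable"])
                    if not (0 <= pct <= 100):
                        raise DataError(f"percent_viable outside [0, 100]: {pct}")
                    obs.append(
                        ViabilityObservation(
                            time=float(row["time_days"]),
                            replicate=int(row["replicate"]),
                            n_tested=100,
                            n_viable=round(pct),
                            viability_override=pct / 100.0,
                        )
                    )
                    continue
                obs.append(
                    ViabilityObservation(
                        time=float(row["time_days"]),
                        replicate=int(row["replicate"]),
                        n_tested=n_tested,
                        n_viable=n_viable,
                    )
                )
            except DataError as exc:
                raise DataError(f"row {rowno} (lot {lot_id!r}): {exc}") from exc
        year = None
        if "collection_year" in group.columns and not group["collection_year"].isna().all():
            year = int(group["collection_year"].iloc[0])
        habitat = None
        if "habitat" in group.columns and not group["habitat"].isna().all():
            habitat = str(group["habitat"].iloc[0])
        assays.append(
            ViabilityAssay(
                lot_id=str(lot_id),
                observations=obs,
                collection_year=year,
                habitat=habitat,
            )
        )
    return assays
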