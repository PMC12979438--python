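"""CSV/JSON interfaces shared by the CLI and scripts.

CSV dialect: comma-separated, UTF-8, mandatory header, ``.`` decimal mark.
Times are in days at every interface.  Every JSON report carries the
package version, a hash of the run configuration and the RNG seeds used,
so a run can be reproduced from its own output.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "load_age_l50_table",
    "load_germination_table",
    "write_assay_csv",
    "write_report",
    "report_payload",
]


def load_age_l50_table(source) -> pd.DataFrame:
    """Read an ``age_years,l50_days`` CSV, validating both columns."""
    df = pd.read_csv(source)
    missing = [c for c in ("age_years", "l50_days") if c not in df.columns]
    if missing:
        raise DataError(f"age-L50 table is missing columns: {missing}")
    if (df["age_years"] < 0).any() or (df["l50_days"] < 0).any():
        bad = df[(df["age_years"] < 0) | (df["l50_days"] < 0)].index[0] + 1
        raise DataError(f"row {bad}: ages and L50 values must be >= 0")
    return df[["age_years", "l50_days"]].astype(float)


def load_germination_table(source) -> dict:
    """Read a ``cohort,replicate,percent_germinated`` CSV into cohort lists."""
    df = pd.read_csv(source)
    missing = [c for c in ("cohort", "percent_germinated") if c not in df.columns]
    if missing:
        raise DataError(f"germination table is missing columns: {missing}")
    out = {}
    for cohort, grp in df.groupby("cohort", sort=True):
        vals = grp["percent_germinated"].astype(float).tolist()
        if any(not (0 <= v <= 100) for v in vals):
            raise DataError(f"cohort {cohort!r}: percentages outside [0, 100]")
        out[str(cohort)] = vals
    return out


def write_assay_csv(assays, path):
    """Write assays in the canonical viability-table layout."""
    frames = [a.to_frame() for a in assays]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return None if obj != obj else ("inf" if obj > 0 else "-inf")
    return obj


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("seedlong")
    except Exception:
        return "unknown"


def report_payload(body: dict, config: dict = None, rng_seed=None) -> dict:
    """Wrap a report body with version, config hash and seed provenance."""
    config = _jsonable(config or {})
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode("utf-8")
    ).hexdigest()[:16]
    return {
        "package": "seedlong",
        "version": _package_version(),
        "config": config,
        "config_hash": digest,
        "rng_seed": rng_seed,
        **_jsonable(body),
    }


def write_report(path, body: dict, config: dict = None, rng_seed=None) -> dict:
    """Write a JSON report (see :func:`report_payload`) and return the payload."""
    payload = report_payload(body, config=config, rng_seed=rng_seed)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload
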