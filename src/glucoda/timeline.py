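"""Patient timelines: glucose self-measurements plus meal records, and the
delimited-text readers/writers for them.

File schemas (comma-separated, UTF-8, header row required):

* measurements: ``time_min,glucose_mgdl,tag`` with tag in {pre, post, random, ""}
* meals: ``time_min,carbs_g``
* flat config: one ``namespaced.key=value`` per line, ``#`` comments allowed
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "PatientTimeline",
    "read_timeline",
    "write_timeline",
    "read_config",
    "write_config",
]

VALID_TAGS = {"pre", "post", "random", ""}


@dataclass
class PatientTimeline:
    """Time-sorted glucose measurements and meal records for one subject.

    ``measurements`` columns: time_min, glucose_mgdl, tag.
    ``meals`` columns: time_min, carbs_g.  Times are minutes from the
    timeline origin; ``origin`` is informational only.
    """

    measurements: pd.DataFrame
    meals: pd.DataFrame
    origin: str = ""

    def __post_init__(self) -> None:
        m = self.measurements.reset_index(drop=True)
        if list(m.columns) != ["time_min", "glucose_mgdl", "tag"]:
            m = m.rename(columns=dict(zip(m.columns, ["time_min", "glucose_mgdl", "tag"])))
        m["tag"] = m["tag"].fillna("").astype(str)
        for i, row in m.iterrows():
            if not np.isfinite(row.time_min):
                raise ValidationError(f"measurement row {i}: non-finite time")
            if not np.isfinite(row.glucose_mgdl) or not (0 < row.glucose_mgdl < 1000):
                raise ValidationError(
                    f"measurement row {i}: glucose {row.glucose_mgdl} outside (0, 1000) mg/dl"
                )
            if row.tag not in VALID_TAGS:
                raise ValidationError(f"measurement row {i}: unknown tag {row.tag!r}")
        ml = self.meals.reset_index(drop=True)
        if list(ml.columns) != ["time_min", "carbs_g"]:
            ml = ml.rename(columns=dict(zip(ml.columns, ["time_min", "carbs_g"])))
        for i, row in ml.iterrows():
            if not np.isfinite(row.time_min):
                raise ValidationError(f"meal row {i}: non-finite time")
            if not np.isfinite(row.carbs_g) or row.carbs_g < 0:
                raise ValidationError(f"meal row {i}: carbs {row.carbs_g} must be >= 0")
        # ties keep file order (stable sort); the filter processes them in order
        self.measurements = m.sort_values("time_min", kind="stable").reset_index(drop=True)
        self.meals = ml.sort_values("time_min", kind="stable").reset_index(drop=True)

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def span(self) -> tuple:
        """(first, last) time over both streams, in minutes."""
        times = np.concatenate([
            self.measurements["time_min"].to_numpy(float),
            self.meals["time_min"].to_numpy(float),
        ])
        if times.size == 0:
            return (0.0, 0.0)
        return float(times.min()), float(times.max())

    def meal_array(self) -> np.ndarray:
        """Meals as a (k, 2) array of (time_min, carbs_g) for the integrators."""
        return self.meals[["time_min", "carbs_g"]].to_numpy(float).reshape(-1, 2)


def _read_csv(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}; header must be {columns}")
    out = {}
    for c in columns:
        if c == "tag":
            out[c] = df[c].astype(str)
            continue
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.index[vals.isna() & (df[c] != "")]
        if len(bad):
            raise ValidationError(f"{path} line {bad[0] + 2}: cannot parse {c}={df[c][bad[0]]!r}")
        out[c] = vals
    return pd.DataFrame(out)


def read_timeline(measurements_path, meals_path) -> PatientTimeline:
    """Parse, validate and sort a patient timeline from its two CSV files."""
    meas = _read_csv(measurements_path, ["time_min", "glucose_mgdl", "tag"])
    meals = _read_csv(meals_path, ["time_min", "carbs_g"])
    try:
        return PatientTimeline(meas, meals, origin=str(measurements_path))
    except ValidationError as e:
        # convert row index to file line number (header is line 1)
        raise ValidationError(f"{measurements_path}/{meals_path}: {e}") from None


def write_timeline(timeline: PatientTimeline, measurements_path, meals_path) -> None:
    timeline.measurements.to_csv(measurements_path, index=False)
    timeline.meals.to_csv(meals_path, index=False)


def read_config(path) -> dict:
    """Flat ``namespaced.key=value`` config; values parsed as float when possible."""
    cfg: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path} line {lineno}: expected key=value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        try:
            cfg[key] = float(value)
        except ValueError:
            cfg[key] = value
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text("".join(f"{k}={v}\n" for k, v in sorted(cfg.items())))
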