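"""From classified tracks to per-sample counts, densities and survival.

A trawl sample is one 10-minute tow at a fixed combination of the three
study factors — tide (flood/ebb), horizontal channel position
(center/side) and vertical stratum (upper/lower half of the water
column) — with the filtered water volume measured by flowmeter.  Counts
are fish tracks whose first detection falls inside the sample window at
or above a chosen identification confidence; densities are expressed
per 10,000 m^3 of water filtered.  The survival accounting compares
fish that passed through the open codend alive against fish found
entangled in the net mesh.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DENSITY_SCALE_M3 = 10_000.0
SAMPLE_DURATION_MIN = 10.0

TIDE_LEVELS = ("flood", "ebb")
HORIZONTAL_LEVELS = ("center", "side")
VERTICAL_LEVELS = ("upper", "lower")

#: sensor CSV schema (one row per reading)
SENSOR_COLUMNS = [
    "timestamp", "latitude", "longitude", "depth_m",
    "tilt_deg", "roll_deg", "pitch_deg", "internal_temp_c", "humidity_pct",
]


@dataclass
class SensorRecord:
    timestamp: pd.Timestamp
    latitude: float
    longitude: float
    depth_m: float
    tilt_deg: float = 0.0
    roll_deg: float = 0.0
    pitch_deg: float = 0.0
    internal_temp_c: float = 20.0
    humidity_pct: float = 30.0


def read_sensors(path: str | Path) -> pd.DataFrame:
    """Read a sensor CSV (ISO-8601 UTC timestamps); validates ordering."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(SENSOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sensor file missing columns: {sorted(missing)}")
    if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
        raise ValueError("sensor timestamps must be strictly increasing")
    return df


@dataclass
class TrawlSample:
    sample_id: str
    tide: str
    horizontal: str
    vertical: str
    start: pd.Timestamp
    end: pd.Timestamp
    volume_m3: float
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tide not in TIDE_LEVELS:
            raise ValueError(f"{self.sample_id}: tide must be one of {TIDE_LEVELS}")
        if self.horizontal not in HORIZONTAL_LEVELS:
            raise ValueError(
                f"{self.sample_id}: horizontal must be one of {HORIZONTAL_LEVELS}"
            )
        if self.vertical not in VERTICAL_LEVELS:
            raise ValueError(
                f"{self.sample_id}: vertical must be one of {VERTICAL_LEVELS}"
            )
        if self.volume_m3 <= 0:
            raise ValueError(f"{self.sample_id}: volume_m3 must be > 0")

    @property
    def densities(self) -> dict[str, float]:
        return {s: density(c, self.volume_m3) for s, c in self.counts.items()}


@dataclass
class SurvivalSummary:
    passed: int
    entangled: int

    @property
    def total(self) -> int:
        return self.passed + self.entangled

    @property
    def percent_survived(self) -> int:
        return round(100 * self.passed / self.total)


def assign_stratum(depths_m, water_depth_m: float) -> str:
    """Classify a deployment as upper or lower half of the water column.

    The median deployment depth is compared with half the water depth;
    exactly mid-depth counts as lower (documented tie rule).  Tows
    target roughly 1/4 depth (upper) or 3/4 depth (lower).
    """
    if water_depth_m is None or not np.isfinite(water_depth_m) or water_depth_m <= 0:
        raise ValueError(f"invalid water depth: {water_depth_m}")
    depths = np.asarray(depths_m, dtype=float)
    if depths.size == 0:
        raise ValueError("need at least one depth reading")
    return "upper" if np.median(depths) < water_depth_m / 2.0 else "lower"


def windowed_counts(identifications: pd.DataFrame,
                    window: tuple[pd.Timestamp, pd.Timestamp],
                    min_confidence: float = 1.0) -> dict[str, int]:
    """Count identified tracks per species inside a sample window.

    ``identifications`` needs columns species, confidence, first_time;
    a track is counted when its first detection time lies in
    [start, end) and its confidence is >= ``min_confidence``.  Transit
    to and from depth is outside the window and therefore excluded.
    """
    start, end = window
    if end <= start:
        raise ValueError(f"malformed window: {start} .. {end}")
    if identifications.empty:
        return {}
    t = pd.to_datetime(identifications["first_time"])
    sel = (t >= start) & (t < end) & (
        identifications["confidence"] >= min_confidence
    )
    return identifications.loc[sel, "species"].value_counts().to_dict()


def density(count: int, volume_m3: float) -> float:
    """Fish per 10,000 m^3 of water filtered."""
    if volume_m3 <= 0:
        raise ValueError(f"volume_m3 must be > 0, got {volume_m3}")
    return count / volume_m3 * DENSITY_SCALE_M3


def survival_summary(passed: int, entangled: int) -> SurvivalSummary:
    """Survival accounting: fish passing through alive vs entangled."""
    if passed < 0 or entangled < 0:
        raise ValueError("counts must be non-negative")
    if passed + entangled == 0:
        raise ValueError("total must be > 0")
    return SurvivalSummary(passed=int(passed), entangled=int(entangled))


def build_count_dataset(samples: list[TrawlSample], species: str) -> pd.DataFrame:
    """One row per sample: y = count of ``species``, volume, factor levels.

    Row order is stable by sample_id.  The result is the response table
    consumed by :mod:`fincam.count_models`.
    """
    if not samples:
        raise ValueError("no samples")
    rows = []
    for s in sorted(samples, key=lambda s: s.sample_id):
        rows.append({
            "sample_id": s.sample_id,
            "y": int(s.counts.get(species, 0)),
            "volume_m3": s.volume_m3,
            "T": s.tide, "H": s.horizontal, "V": s.vertical,
        })
    return pd.DataFrame(rows)


# -- serialization ----------------------------------------------------------

def write_count_dataset(path: str | Path, data: pd.DataFrame) -> None:
    data.to_csv(path, index=False)


def read_count_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = {"y", "volume_m3", "T", "H", "V"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"count dataset missing columns: {sorted(missing)}")
    return df


def read_trawl_metadata(path: str | Path) -> dict:
    """Read trawl metadata JSON (tide, horizontal, water_depth_m,
    volume_m3, window start/end)."""
    meta = json.loads(Path(path).read_text())
    for key in ("tide", "horizontal", "water_depth_m", "volume_m3",
                "start", "end"):
        if key not in meta:
            raise ValueError(f"trawl metadata missing {key!r}")
    return meta


def write_survival(path: str | Path, summary: SurvivalSummary) -> None:
    Path(path).write_text(json.dumps({
        "passed": summary.passed,
        "entangled": summary.entangled,
        "total": summary.total,
        "percent_survived": summary.percent_survived,
    }, indent=2))
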