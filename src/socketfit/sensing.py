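"""Sensor-region aggregation and pressure normalization.

The socket wall is divided into named anatomical regions, each a band
bounded by ``(z_min, z_max, theta_min, theta_max)`` in the cylindrical
convention of :mod:`socketfit.geometry`.  Pressure samples (sensor pads or a
sampled donning-pressure field) falling inside a region are pooled and
averaged into one mean value per region — the decision-support input unit.

Normalization expresses a region's mean pressure as the percentage above the
region's pressure-tolerance threshold: ``100 * (p - T) / T`` (negative below
threshold).  Thresholds are calibrated from a benchmark comfortable socket.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TOLERANCE_CLASSES = ("sensitive", "tolerant")


@dataclass(frozen=True)
class AnatomicalRegion:
    """A named band on the socket wall with a pressure-tolerance class."""

    region_id: str
    name: str
    z_min: float
    z_max: float
    theta_min: float
    theta_max: float
    tolerance_class: str = "tolerant"
    threshold: float = 1.0  # kPa

    def __post_init__(self):
        if not self.z_min < self.z_max:
            raise ValueError(f"{self.region_id}: z_min must be < z_max")
        if self.tolerance_class not in TOLERANCE_CLASSES:
            raise ValueError(f"{self.region_id}: unknown tolerance class {self.tolerance_class!r}")
        if not self.threshold > 0:
            raise ValueError(f"{self.region_id}: threshold must be > 0")
        span = self.angular_extent
        if not 0 < span <= 360:
            raise ValueError(f"{self.region_id}: angular extent must be in (0, 360]")

    @property
    def angular_extent(self) -> float:
        span = (self.theta_max - self.theta_min) % 360.0
        return 360.0 if span == 0 else span

    def contains(self, h, theta) -> np.ndarray:
        """Membership of (h, theta) samples; half-open on both max edges,
        wrap-aware in theta (theta_min > theta_max wraps through 0)."""
        h = np.asarray(h, dtype=float)
        theta = np.asarray(theta, dtype=float) % 360.0
        in_h = (h >= self.z_min) & (h < self.z_max)
        off = (theta - self.theta_min) % 360.0
        in_t = off < self.angular_extent
        return in_h & in_t


@dataclass(frozen=True)
class RegionPressure:
    """Mean pressure (kPa) for one region; ``n_samples == 0`` flags a region
    with no contributing sensor (reported as 0 kPa, not missing)."""

    region_id: str
    pressure: float
    n_samples: int = 1

    def __post_init__(self):
        if self.pressure < 0:
            raise ValueError(f"{self.region_id}: pressure must be >= 0")
        if self.n_samples < 0:
            raise ValueError(f"{self.region_id}: n_samples must be >= 0")

    @property
    def no_contact(self) -> bool:
        return self.n_samples == 0


@dataclass
class PressureField:
    """Samples of interface pressure over the inner wall: (h, theta, p)."""

    h: np.ndarray = field(default_factory=lambda: np.empty(0))
    theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    pressure: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float).ravel()
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.pressure = np.asarray(self.pressure, dtype=float).ravel()
        if not (len(self.h) == len(self.theta) == len(self.pressure)):
            raise ValueError("h, theta and pressure must have equal length")
        if np.any(self.pressure < 0):
            raise ValueError("pressures must be >= 0")


def region_mean_pressures(
    field: PressureField, regions: list[AnatomicalRegion]
) -> list[RegionPressure]:
    """Pool field samples per region and average (one mean per region).

    Regions with no samples report pressure 0 with ``n_samples = 0`` — the
    non-contacting-sensor case — rather than missing data.
    """
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate region_ids: {dupes}")
    out = []
    for region in regions:
        mask = region.contains(field.h, field.theta) if len(field.h) else np.zeros(0, bool)
        n = int(mask.sum())
        mean = float(field.pressure[mask].mean()) if n else 0.0
        out.append(RegionPressure(region.region_id, mean, n))
    return out


def normalize_pressure(pressure: float, threshold: float, form: str = "relative",
                       p_ref: float | None = None) -> float:
    """Percentage of pressure above the threshold.

    ``relative`` (default): ``100 * (p - T) / T`` — scale-free across
    regions.  ``absolute``: ``100 * (p - T) / p_ref`` for a fixed reference
    pressure.  Negative values mean below threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    if form == "relative":
        return 100.0 * (pressure - threshold) / threshold
    if form == "absolute":
        if p_ref is None or p_ref <= 0:
            raise ValueError("absolute form requires p_ref > 0")
        return 100.0 * (pressure - threshold) / p_ref
    raise ValueError(f"unknown normalization form {form!r}")


#: Default threshold scale per tolerance class.  A sensitive region's
#: threshold sits at its nominal (comfortable) pressure, so nominal
#: normalizes to 0%; a tolerant region tolerates well above nominal, so its
#: threshold is placed at 5/3 of nominal and nominal normalizes to -40%,
#: the middle of the tolerant "normal" membership plateau.
DEFAULT_CLASS_SCALE = {"sensitive": 1.0, "tolerant": 5.0 / 3.0}


def calibrate_thresholds(
    nominal: list[RegionPressure],
    regions: list[AnatomicalRegion] | None = None,
    scale: float | dict = 1.0,
    floor: float = 1.0,
    variant_factor: float = 1.0,
) -> dict[str, float]:
    """Per-region thresholds from a benchmark (comfortable) socket.

    ``threshold_i = max(nominal_i, floor) * scale_i * variant_factor`` where
    ``scale`` is a scalar or a per-tolerance-class mapping (requires
    ``regions``).  ``variant_factor`` produces the low/medium/high
    rectification variants: raising every threshold weakens the normalized
    pressures and hence the rectification the rules decide.
    """
    if not nominal:
        raise ValueError("nominal pressures must be non-empty")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    classes = {r.region_id: r.tolerance_class for r in regions} if regions else {}
    out = {}
    for rp in nominal:
        if isinstance(scale, dict):
            cls = classes.get(rp.region_id, "tolerant")
            s = scale[cls]
        else:
            s = float(scale)
        out[rp.region_id] = max(rp.pressure, floor) * s * variant_factor
    return out


# ---------------------------------------------------------------------------
# tabular I/O (region files per the sensor-deployment table schema)

_REGION_COLS = ["region_id", "name", "z_min", "z_max", "theta_min", "theta_max",
                "tolerance_class", "threshold_kPa"]


def load_regions(path) -> list[AnatomicalRegion]:
    df = pd.read_csv(path)
    missing = set(_REGION_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"region file {path!s} missing columns: {sorted(missing)}")
    return [
        AnatomicalRegion(
            region_id=str(row.region_id), name=str(row.name_col),
            z_min=float(row.z_min), z_max=float(row.z_max),
            theta_min=float(row.theta_min), theta_max=float(row.theta_max),
            tolerance_class=str(row.tolerance_class), threshold=float(row.threshold_kPa),
        )
        for row in df.rename(columns={"name": "name_col"}).itertuples(index=False)
    ]


def save_regions(regions: list[AnatomicalRegion], path) -> None:
    pd.DataFrame(
        [
            [r.region_id, r.name, r.z_min, r.z_max, r.theta_min, r.theta_max,
             r.tolerance_class, r.threshold]
            for r in regions
        ],
        columns=_REGION_COLS,
    ).to_csv(path, index=False)


def load_pressure_field(path) -> PressureField:
    df = pd.read_csv(path)
    for col in ("h_mm", "theta_deg", "pressure_kPa"):
        if col not in df.columns:
            raise ValueError(f"field file {path!s} missing column {col!r}")
    return PressureField(df["h_mm"].to_numpy(), df["theta_deg"].to_numpy(),
                         df["pressure_kPa"].to_numpy())


def load_region_pressures(path) -> list[RegionPressure]:
    df = pd.read_csv(path)
    for col in ("region_id", "pressure_kPa"):
        if col not in df.columns:
            raise ValueError(f"pressure file {path!s} missing column {col!r}")
    n = df["n_samples"] if "n_samples" in df.columns else pd.Series([1] * len(df))
    return [
        RegionPressure(str(r), float(p), int(k))
        for r, p, k in zip(df["region_id"], df["pressure_kPa"], n)
    ]


def save_region_pressures(pressures: list[RegionPressure], path) -> None:
    pd.DataFrame(
        [[rp.region_id, rp.pressure, rp.n_samples] for rp in pressures],
        columns=["region_id", "pressure_kPa", "n_samples"],
    ).to_csv(path, index=False)
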