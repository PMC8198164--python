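"""Synthetic donning-pressure surrogate and the closed rectification loop.

The surrogate is an explicit, deliberately simple spring-foundation model of
how a transfemoral stump loads a socket wall after donning.  It is NOT a
contact-mechanics simulation; it is calibrated to reproduce the qualitative
behaviour a loose socket exhibits — the stump slides distally, the
distal-end pressure rises while proximal regions (notably Scarpa's
triangle) unload — and the converse effect of an antero-lateral wall
thickening, which arrests the slide (distal pressure falls) at the cost of
elevated proximal pressures.

Model, per region i with nominal baseline pressure b_i:

* slide  = max(0, slide_gain * A% - relief * sum_z w_z * t_z)   [mm]
* distal-end:      p = b + transfer * slide
* all other regions: p = max(0, b + stiffness * (sum_z coupling_iz * t_z - slack))
  with slack = slack_coeff * slide

where A% is the cross-sectional area increase in percent and t_z the
plateau thickening (mm) applied to deformation zone z.  All coefficients
are configurable; optional Gaussian noise (off by default, the reference
simulation is deterministic) supports robustness experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .defaults import (
    DEFAULT_BASELINES,
    DEFAULT_REGIONS,
    DISTAL,
    default_config,
)
from .fuzzy import DssOutput, FuzzySystemConfig, infer
from .rectify import DEFAULT_ZONE_ROLES
from .sensing import (
    DEFAULT_CLASS_SCALE,
    AnatomicalRegion,
    RegionPressure,
    calibrate_thresholds,
)

#: Fraction of each zone's plateau magnitude felt by a coupled region
#: (the logistic/height blend averages well below the plateau).
DEFAULT_COUPLINGS = {
    "S1E2": {"anterior": 0.5},                      # Scarpa's triangle
    "S1E4": {"anterior": 0.4},                      # anterior proximal
    "S2E5": {"anterior": 0.1},                      # pubic ramus
    "S3E1": {"anterior": 0.2},                      # ischial seat
    "S3E6": {"anterior": 0.1},                      # posterior proximal
    "S4E2": {"lateral": 0.5, "anterior": 0.1},      # lateral mid
    "S5E8": {"lateral": 0.5, "anterior": 0.1},      # lateral proximal
}


@dataclass(frozen=True)
class SocketState:
    """Geometric state fed to the surrogate: how loose, how rectified."""

    area_increase: float = 0.0          # fraction, e.g. 0.05
    thickening: dict = field(default_factory=dict)  # zone role -> plateau mm

    def __post_init__(self):
        if self.area_increase < 0:
            raise ValueError("area_increase must be >= 0")
        if any(v < 0 for v in self.thickening.values()):
            raise ValueError("thickenings must be >= 0")


@dataclass(frozen=True)
class SurrogateParams:
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    distal_region: str = DISTAL
    transfer: float = 8.0        # kPa of distal pressure per mm of slide
    stiffness: float = 8.0       # kPa per mm of proximal interference
    slide_gain: float = 1.2      # mm of slide per % of area increase
    slack_coeff: float = 0.8     # mm of proximal slack per mm of slide
    relief: float = 0.5          # mm of slide removed per weighted mm thickening
    zone_weights: dict = field(default_factory=lambda: {"anterior": 0.5, "lateral": 0.5})
    couplings: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COUPLINGS.items()})
    noise_sd: float = 0.0        # kPa, optional Gaussian measurement noise
    seed: int = 0

    def __post_init__(self):
        for name in ("transfer", "stiffness", "slide_gain", "slack_coeff", "relief"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.baselines.values()):
            raise ValueError("baseline pressures must be >= 0")


def simulate_pressures(
    state: SocketState,
    params: SurrogateParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[RegionPressure]:
    """Deterministic per-region pressures for a socket state.

    With ``noise_sd > 0`` a generator seeded from ``params.seed`` (or the one
    passed in) adds Gaussian noise before clamping at zero.  A region clamped
    to 0 kPa is reported with ``n_samples = 0`` (non-contacting sensor).
    """
    p = params or SurrogateParams()
    area_pct = 100.0 * state.area_increase
    weighted_thk = sum(
        p.zone_weights.get(zone, 0.0) * t for zone, t in state.thickening.items()
    )
    slide = max(0.0, p.slide_gain * area_pct - p.relief * weighted_thk)
    slack = p.slack_coeff * slide

    if p.noise_sd > 0 and rng is None:
        rng = np.random.default_rng(p.seed)

    out = []
    for region_id, baseline in p.baselines.items():
        if region_id == p.distal_region:
            pressure = baseline + p.transfer * slide
        else:
            interference = sum(
                c * state.thickening.get(zone, 0.0)
                for zone, c in p.couplings.get(region_id, {}).items()
            )
            pressure = baseline + p.stiffness * (interference - slack)
        if p.noise_sd > 0:
            pressure += float(rng.normal(0.0, p.noise_sd))
        pressure = max(0.0, pressure)
        out.append(RegionPressure(region_id, pressure, 0 if pressure == 0.0 else 1))
    return out


#: Threshold variant factors: raising every threshold weakens the normalized
#: pressure signal, so the rules decide progressively smaller rectification.
DEFAULT_VARIANTS = {"high": 1.0, "medium": 2.5, "low": 5.0}


def _excess(pressures: list[RegionPressure], thresholds: dict[str, float]) -> dict[str, float]:
    return {
        rp.region_id: 100.0 * (rp.pressure - thresholds[rp.region_id]) / thresholds[rp.region_id]
        for rp in pressures
    }


def closed_loop_demo(
    params: SurrogateParams | None = None,
    config: FuzzySystemConfig | None = None,
    regions: list[AnatomicalRegion] | None = None,
    area_increase: float = 0.05,
    variants: dict[str, float] | None = None,
    class_scale: dict | None = None,
    floor: float = 1.0,
) -> dict:
    """The full offline loop: nominal -> calibrate thresholds -> loose ->
    infer (per threshold variant) -> rectify -> re-simulate.

    Returns a JSON-serializable report with per-variant actions, pressures
    and the distal-vs-proximal trade-off summary.  Everything is a
    deterministic function of the inputs (and the seed, if noise is on).
    """
    params = params or SurrogateParams()
    regions = DEFAULT_REGIONS if regions is None else regions
    config = default_config(regions) if config is None else config
    variants = DEFAULT_VARIANTS if variants is None else variants
    class_scale = DEFAULT_CLASS_SCALE if class_scale is None else class_scale

    nominal = simulate_pressures(SocketState(), params)
    base_thresholds = calibrate_thresholds(nominal, regions, scale=class_scale, floor=floor)
    loose = simulate_pressures(SocketState(area_increase=area_increase), params)

    report: dict = {
        "seed": params.seed,
        "area_increase": area_increase,
        "nominal_pressures": {rp.region_id: rp.pressure for rp in nominal},
        "loose_pressures": {rp.region_id: rp.pressure for rp in loose},
        "base_thresholds": dict(base_thresholds),
        "variants": {},
    }

    distal = params.distal_region
    for name, factor in variants.items():
        thresholds = {rid: t * factor for rid, t in base_thresholds.items()}
        output: DssOutput = infer(loose, config, thresholds)
        thickening: dict[str, float] = {}
        for action in output.actions:
            role = DEFAULT_ZONE_ROLES.get(action.zone)
            if role is not None:
                thickening[role] = max(thickening.get(role, 0.0), action.magnitude_mm)
        rectified = simulate_pressures(
            SocketState(area_increase=area_increase, thickening=thickening), params
        )
        excess = _excess(rectified, base_thresholds)
        proximal_excess = max(v for k, v in excess.items() if k != distal)
        report["variants"][name] = {
            "variant_factor": factor,
            "thresholds": thresholds,
            "actions": [a.as_dict() for a in output.actions],
            "rule_activations": output.rule_activations,
            "socket_too_short": output.socket_too_short,
            "thickening": thickening,
            "rectified_pressures": {rp.region_id: rp.pressure for rp in rectified},
            "excess_pct": excess,
            "distal_excess_pct": excess[distal],
            "proximal_excess_pct": proximal_excess,
            "max_excess_pct": max(excess.values()),
        }

    best = min(report["variants"], key=lambda n: report["variants"][n]["max_excess_pct"])
    report["tradeoff"] = {
        "best_variant": best,
        "summary": {
            n: {
                "distal_excess_pct": v["distal_excess_pct"],
                "proximal_excess_pct": v["proximal_excess_pct"],
                "max_excess_pct": v["max_excess_pct"],
            }
            for n, v in report["variants"].items()
        },
    }
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def report_pressures_csv(report: dict, path) -> None:
    """Per-region pressures per socket variant as a tidy CSV."""
    import pandas as pd

    rows = []
    for rid, p in report["nominal_pressures"].items():
        rows.append(["nominal", rid, p])
    for rid, p in report["loose_pressures"].items():
        rows.append(["loose", rid, p])
    for name, v in report["variants"].items():
        for rid, p in v["rectified_pressures"].items():
            rows.append([f"rectified_{name}", rid, p])
    pd.DataFrame(rows, columns=["socket", "region_id", "pressure_kPa"]).to_csv(path, index=False)


def plot_report(report: dict, path) -> None:
    """Grouped bar chart of per-region pressures per socket variant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = list(report["nominal_pressures"])
    series = {"nominal": report["nominal_pressures"], "loose": report["loose_pressures"]}
    for name, v in report["variants"].items():
        series[f"rectified ({name})"] = v["rectified_pressures"]
    x = np.arange(len(regions))
    width = 0.8 / len(series)
    fig, ax = plt.subplots(figsize=(10, 4))
    for i, (label, vals) in enumerate(series.items()):
        ax.bar(x + i * width, [vals[r] for r in regions], width, label=label)
    ax.set_xticks(x + 0.4, regions)
    ax.set_ylabel("pressure (kPa)")
    ax.set_xlabel("region")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
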