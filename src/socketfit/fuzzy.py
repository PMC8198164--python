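"""Mamdani-style fuzzy inference engine for socket rectification.

The engine follows the classic three-block layout: fuzzification of
normalized region pressures through per-region membership functions,
rule evaluation (min for AND, ``1 - mu`` for negation, min implication),
max aggregation per output zone, and centroid defuzzification of the
aggregated thickness set into a crisp rectification magnitude in mm.

Input linguistic labels are {low, normal, high, very_high} over normalized
pressure (percent above the region threshold); output labels are
{small, medium, large, very_large} over pad/wall thickness in mm.  Rules
whose consequent is the categorical "socket too short" outcome raise a flag
instead of contributing to a zone's thickness set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sensing import RegionPressure, normalize_pressure

INPUT_LABELS = ("low", "normal", "high", "very_high")
OUTPUT_LABELS = ("small", "medium", "large", "very_large")
SOCKET_TOO_SHORT = "socket_too_short"


class ConfigError(ValueError):
    """Raised for inconsistent fuzzy-system configuration."""


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership function (trapezoid/triangle/shoulder).

    ``xs`` are non-decreasing breakpoints, ``ys`` the degrees at those
    breakpoints; evaluation clamps to the edge values outside the support,
    so shoulders are expressed by their finite edge alone.
    """

    label: str
    xs: tuple[float, ...]
    ys: tuple[float, ...]

    def __post_init__(self):
        xs = tuple(float(x) for x in self.xs)
        ys = tuple(float(y) for y in self.ys)
        if len(xs) != len(ys) or len(xs) < 2:
            raise ConfigError(f"{self.label}: need matching xs/ys of length >= 2")
        if any(b < a for a, b in zip(xs, xs[1:])):
            raise ConfigError(f"{self.label}: breakpoints must be non-decreasing")
        if any(not 0 <= y <= 1 for y in ys):
            raise ConfigError(f"{self.label}: degrees must lie in [0, 1]")
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)

    def degree(self, x):
        return np.interp(x, self.xs, self.ys)

    @classmethod
    def trapezoid(cls, label, a, b, c, d):
        return cls(label, (a, b, c, d), (0.0, 1.0, 1.0, 0.0))

    @classmethod
    def triangle(cls, label, a, b, c):
        return cls(label, (a, b, c), (0.0, 1.0, 0.0))

    @classmethod
    def shoulder_left(cls, label, a, b):
        """1 for x <= a, falling to 0 at b."""
        return cls(label, (a, b), (1.0, 0.0))

    @classmethod
    def shoulder_right(cls, label, a, b):
        """0 for x <= a, rising to 1 at b."""
        return cls(label, (a, b), (0.0, 1.0))


MFSet = dict[str, MembershipFunction]


@dataclass(frozen=True)
class Term:
    """One antecedent atom: the input's degree in a label (or the max degree
    over several labels, e.g. 'high pressure' covering high and very_high),
    optionally negated with the standard fuzzy complement 1 - mu."""

    input: str
    labels: tuple[str, ...]
    negated: bool = False

    def __post_init__(self):
        labels = (self.labels,) if isinstance(self.labels, str) else tuple(self.labels)
        if not labels:
            raise ConfigError("term needs at least one label")
        object.__setattr__(self, "labels", labels)

    def degree(self, fuzzified: dict[str, dict[str, float]]) -> float:
        if self.input not in fuzzified:
            raise ConfigError(f"rule references missing input {self.input!r}")
        mu = max(fuzzified[self.input].get(lbl, 0.0) for lbl in self.labels)
        return 1.0 - mu if self.negated else mu


@dataclass(frozen=True)
class Rule:
    """IF <antecedent conjunction> THEN <zone IS magnitude> | <flag>."""

    name: str
    antecedent: tuple[Term, ...]
    zone: str | None = None
    magnitude: str | None = None
    flag: str | None = None

    def __post_init__(self):
        if not self.antecedent:
            raise ConfigError(f"rule {self.name}: empty antecedent")
        has_zone = self.zone is not None and self.magnitude is not None
        if has_zone == (self.flag is not None):
            raise ConfigError(f"rule {self.name}: exactly one consequent required")

    def strength(self, fuzzified) -> float:
        return min(t.degree(fuzzified) for t in self.antecedent)


@dataclass(frozen=True)
class ZoneSpec:
    """Where a rectification zone sits on the socket wall (for reporting the
    action location) and which physical action realizes it."""

    zone: str
    theta_start: float
    theta_end: float
    h_min: float
    h_max: float
    r_ref: float = float("nan")
    action_type: str = "pad"

    @property
    def theta_center(self) -> float:
        span = (self.theta_end - self.theta_start) % 360.0 or 360.0
        return (self.theta_start + span / 2.0) % 360.0

    @property
    def h_center(self) -> float:
        return 0.5 * (self.h_min + self.h_max)


@dataclass
class FuzzySystemConfig:
    """Complete declarative description of the inference system."""

    input_mfs: dict[str, MFSet]
    output_mfs: MFSet
    rules: tuple[Rule, ...]
    zones: dict[str, ZoneSpec]
    output_domain: tuple[float, float] = (0.0, 36.0)
    defuzz_step: float = 0.1
    lateral_regions: tuple[str, ...] = ()
    flag_threshold: float = 0.5
    and_op: str = "min"
    agg_op: str = "max"
    implication: str = "min"
    defuzz_method: str = "centroid"

    def __post_init__(self):
        lo, hi = self.output_domain
        if not hi > lo:
            raise ConfigError("output domain must be non-degenerate")
        for mf in self.output_mfs.values():
            if mf.xs[0] < lo - 1e-9 or mf.xs[-1] > hi + 1e-9:
                raise ConfigError(f"output set {mf.label} exceeds the output domain")
        for rule in self.rules:
            if rule.zone is not None and rule.zone not in self.zones:
                raise ConfigError(f"rule {rule.name}: unknown zone {rule.zone!r}")
            if rule.magnitude is not None and rule.magnitude not in self.output_mfs:
                raise ConfigError(f"rule {rule.name}: unknown magnitude {rule.magnitude!r}")
        if self.defuzz_method != "centroid":
            raise ConfigError("only centroid defuzzification is implemented")
        if self.and_op != "min" or self.agg_op != "max" or self.implication != "min":
            raise ConfigError("only the min/max/min operator family is implemented")

    @property
    def output_grid(self) -> np.ndarray:
        lo, hi = self.output_domain
        n = int(round((hi - lo) / self.defuzz_step)) + 1
        return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class RectificationAction:
    """One crisp rectification: how thick, where, and by which means."""

    magnitude_mm: float
    zone: str
    theta: float
    h: float
    r: float
    theta_extent: float
    h_extent: float
    action_type: str = "pad"

    def as_dict(self) -> dict:
        return {
            "magnitude_mm": self.magnitude_mm,
            "zone": self.zone,
            "location": {"r": self.r, "theta": self.theta, "h": self.h},
            "extent": {"theta": self.theta_extent, "h": self.h_extent},
            "type": self.action_type,
        }


@dataclass
class DssOutput:
    """Inference result: actions, categorical flags and the explanation."""

    actions: list[RectificationAction]
    socket_too_short: bool
    rule_activations: dict[str, float]
    zone_magnitudes: dict[str, float]
    zone_fired: dict[str, bool]
    normalized_inputs: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "actions": [a.as_dict() for a in self.actions],
            "socket_too_short": self.socket_too_short,
            "rule_activations": self.rule_activations,
            "zone_magnitudes": self.zone_magnitudes,
            "zone_fired": self.zone_fired,
            "normalized_inputs": self.normalized_inputs,
        }


# ---------------------------------------------------------------------------
# engine operations


def fuzzify(x: float, mfs: MFSet) -> dict[str, float]:
    """Degrees of one crisp (normalized) value in every labelled set."""
    return {label: float(mf.degree(x)) for label, mf in mfs.items()}


@dataclass
class RuleEvaluation:
    strengths: dict[str, float]
    zone_aggregates: dict[str, np.ndarray]
    flags: dict[str, float]
    grid: np.ndarray


def evaluate_rules(
    fuzzified: dict[str, dict[str, float]],
    rules: tuple[Rule, ...],
    config: FuzzySystemConfig,
) -> RuleEvaluation:
    """Fire every rule: min over antecedent degrees, min implication (clip
    the consequent set at the firing strength), max aggregation per zone."""
    grid = config.output_grid
    aggregates = {z: np.zeros_like(grid) for z in config.zones}
    strengths: dict[str, float] = {}
    flags: dict[str, float] = {}
    for rule in rules:
        try:
            s = float(rule.strength(fuzzified))
        except ConfigError as exc:
            raise ConfigError(f"rule {rule.name}: {exc}") from exc
        strengths[rule.name] = s
        if rule.flag is not None:
            flags[rule.flag] = max(flags.get(rule.flag, 0.0), s)
        else:
            clipped = np.minimum(s, config.output_mfs[rule.magnitude].degree(grid))
            aggregates[rule.zone] = np.maximum(aggregates[rule.zone], clipped)
    return RuleEvaluation(strengths, aggregates, flags, grid)


def defuzzify(aggregated: np.ndarray, grid: np.ndarray) -> tuple[float, bool]:
    """Centroid of the aggregated set on the discretized output domain.

    Returns ``(magnitude_mm, fired)``; an identically-zero aggregate yields
    0 mm with ``fired = False`` (no rule fired for that zone).
    """
    mass = float(np.sum(aggregated))
    if mass <= 0.0:
        return 0.0, False
    return float(np.sum(aggregated * grid) / mass), True


def lateral_statistics(
    pressures: dict[str, RegionPressure],
    thresholds: dict[str, float],
    lateral_regions: tuple[str, ...],
) -> tuple[float, float]:
    """(normalized level, coefficient of variation) of the lateral-side
    region pressures — the derived inputs of the lateral-wall rule set.

    The uniformity antecedent ('pressure along the lateral side is not
    uniform') is operationalized as the CV of the lateral region means; an
    all-zero lateral side has CV 0 (uniformly uncontacted)."""
    ps = np.array([pressures[r].pressure for r in lateral_regions], dtype=float)
    ts = np.array([thresholds[r] for r in lateral_regions], dtype=float)
    if ps.size == 0:
        return 0.0, 0.0
    level = normalize_pressure(float(ps.mean()), float(ts.mean()))
    cv = float(ps.std() / ps.mean()) if ps.mean() > 1e-9 else 0.0
    return level, cv


def infer(
    region_pressures: list[RegionPressure],
    config: FuzzySystemConfig,
    thresholds: dict[str, float],
) -> DssOutput:
    """Full pipeline: normalize -> fuzzify -> rules -> defuzzify per zone.

    Regions with no contacting sensor carry 0 kPa and therefore normalize
    far below threshold, i.e. they read as 'low' — the intended treatment of
    the non-contact flag.
    """
    by_id = {rp.region_id: rp for rp in region_pressures}
    normalized: dict[str, float] = {}
    fuzzified: dict[str, dict[str, float]] = {}
    needed = {t.input for rule in config.rules for t in rule.antecedent}
    for name in needed:
        if name == "lateral_side":
            level, _ = lateral_statistics(by_id, thresholds, config.lateral_regions)
            normalized[name] = level
        elif name == "lateral_uniformity":
            _, cv = lateral_statistics(by_id, thresholds, config.lateral_regions)
            normalized[name] = cv
        else:
            if name not in by_id:
                raise ConfigError(f"rules reference region {name!r} with no pressure input")
            if name not in thresholds:
                raise ConfigError(f"no threshold configured for region {name!r}")
            normalized[name] = normalize_pressure(by_id[name].pressure, thresholds[name])
        if name not in config.input_mfs:
            raise ConfigError(f"no membership functions configured for input {name!r}")
        fuzzified[name] = fuzzify(normalized[name], config.input_mfs[name])

    evaluation = evaluate_rules(fuzzified, config.rules, config)

    actions: list[RectificationAction] = []
    zone_magnitudes: dict[str, float] = {}
    zone_fired: dict[str, bool] = {}
    for zone, agg in evaluation.zone_aggregates.items():
        magnitude, fired = defuzzify(agg, evaluation.grid)
        zone_magnitudes[zone] = magnitude
        zone_fired[zone] = fired
        if fired and magnitude > 0:
            zs = config.zones[zone]
            actions.append(
                RectificationAction(
                    magnitude_mm=magnitude,
                    zone=zone,
                    theta=zs.theta_center,
                    h=zs.h_center,
                    r=zs.r_ref,
                    theta_extent=(zs.theta_end - zs.theta_start) % 360.0 or 360.0,
                    h_extent=zs.h_max - zs.h_min,
                    action_type=zs.action_type,
                )
            )
    too_short = evaluation.flags.get(SOCKET_TOO_SHORT, 0.0) > config.flag_threshold
    return DssOutput(
        actions=actions,
        socket_too_short=too_short,
        rule_activations=evaluation.strengths,
        zone_magnitudes=zone_magnitudes,
        zone_fired=zone_fired,
        normalized_inputs=normalized,
    )


def fuzzify_pressure(pressure_kpa: float, region_id: str, config: FuzzySystemConfig,
                     thresholds: dict[str, float]) -> dict[str, float]:
    """Convenience: normalize a raw kPa reading against the region threshold
    and fuzzify it with that region's membership family."""
    x = normalize_pressure(pressure_kpa, thresholds[region_id])
    return fuzzify(x, config.input_mfs[region_id])


# ---------------------------------------------------------------------------
# (de)serialization

def config_to_dict(config: FuzzySystemConfig) -> dict:
    def mfset(mfs: MFSet) -> dict:
        return {lbl: {"xs": list(mf.xs), "ys": list(mf.ys)} for lbl, mf in mfs.items()}

    return {
        "input_mfs": {name: mfset(mfs) for name, mfs in config.input_mfs.items()},
        "output_mfs": mfset(config.output_mfs),
        "rules": [
            {
                "name": r.name,
                "antecedent": [
                    {"input": t.input, "labels": list(t.labels), "negated": t.negated}
                    for t in r.antecedent
                ],
                "zone": r.zone,
                "magnitude": r.magnitude,
                "flag": r.flag,
            }
            for r in config.rules
        ],
        "zones": {
            z: {
                "theta_start": zs.theta_start, "theta_end": zs.theta_end,
                "h_min": zs.h_min, "h_max": zs.h_max,
                "r_ref": zs.r_ref, "action_type": zs.action_type,
            }
            for z, zs in config.zones.items()
        },
        "output_domain": list(config.output_domain),
        "defuzz_step": config.defuzz_step,
        "lateral_regions": list(config.lateral_regions),
        "flag_threshold": config.flag_threshold,
    }


def config_from_dict(d: dict) -> FuzzySystemConfig:
    def mfset(dd: dict) -> MFSet:
        return {lbl: MembershipFunction(lbl, tuple(v["xs"]), tuple(v["ys"]))
                for lbl, v in dd.items()}

    rules = tuple(
        Rule(
            name=r["name"],
            antecedent=tuple(
                Term(t["input"], tuple(t["labels"]), bool(t.get("negated", False)))
                for t in r["antecedent"]
            ),
            zone=r.get("zone"),
            magnitude=r.get("magnitude"),
            flag=r.get("flag"),
        )
        for r in d["rules"]
    )
    zones = {z: ZoneSpec(zone=z, **zs) for z, zs in d["zones"].items()}
    return FuzzySystemConfig(
        input_mfs={name: mfset(mm) for name, mm in d["input_mfs"].items()},
        output_mfs=mfset(d["output_mfs"]),
        rules=rules,
        zones=zones,
        output_domain=tuple(d.get("output_domain", (0.0, 36.0))),
        defuzz_step=float(d.get("defuzz_step", 0.1)),
        lateral_regions=tuple(d.get("lateral_regions", ())),
        flag_threshold=float(d.get("flag_threshold", 0.5)),
    )
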