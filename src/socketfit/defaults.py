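"""Default configuration: regions, membership families, rule base, zones.

Membership breakpoints are calibration, not ground truth: the input
families are fixed so that the two published worked examples hold exactly —
a 62 kPa reading at the distal-end (threshold 40 kPa, normalized +55%)
fuzzifies to {high: 0.25, very_high: 0.75} and the same reading at Scarpa's
triangle (threshold 80 kPa, normalized -22.5%) to {normal: 0.75,
high: 0.25}.  Crossing label pairs are complementary on their transition so
degrees sum to 1 there.  The output thickness family is centred on 9/19/29
mm for small/medium/large, matching the low/medium/high rectification
magnitudes the closed-loop demonstration realizes.
"""

from __future__ import annotations

from .fuzzy import (
    FuzzySystemConfig,
    MembershipFunction as MF,
    Rule,
    Term,
    ZoneSpec,
    SOCKET_TOO_SHORT,
)
from .sensing import AnatomicalRegion

# --- anatomical regions (sensor-deployment stand-in; synthetic Table-A2-style
# schema for the default synthetic socket, lengths in mm, angles clockwise
# from the proximal lateral brim reference) ---------------------------------

DEFAULT_REGIONS = [
    AnatomicalRegion("S5E3", "distal-end", 260.0, 300.0, 0.0, 360.0, "sensitive", 40.0),
    AnatomicalRegion("S1E2", "scarpa_triangle", 30.0, 110.0, 280.0, 340.0, "tolerant", 80.0),
    AnatomicalRegion("S1E4", "anterior_proximal", 20.0, 100.0, 250.0, 290.0, "tolerant", 60.0),
    AnatomicalRegion("S2E5", "pubic_ramus", 0.0, 60.0, 190.0, 230.0, "sensitive", 35.0),
    AnatomicalRegion("S3E1", "ischial_seat", 0.0, 50.0, 100.0, 150.0, "tolerant", 100.0),
    AnatomicalRegion("S3E6", "posterior_proximal", 50.0, 120.0, 90.0, 160.0, "tolerant", 66.7),
    AnatomicalRegion("S4E2", "lateral_mid", 100.0, 180.0, 330.0, 30.0, "tolerant", 58.3),
    AnatomicalRegion("S5E8", "lateral_proximal", 20.0, 100.0, 330.0, 30.0, "tolerant", 63.3),
]

#: Nominal (comfortable benchmark socket) donning pressures, kPa.  With the
#: default per-class calibration scales (sensitive 1.0, tolerant 5/3) these
#: reproduce the default thresholds above.
DEFAULT_BASELINES = {
    "S5E3": 40.0,   # distal-end
    "S1E2": 48.0,   # Scarpa's triangle
    "S1E4": 36.0,   # anterior proximal
    "S2E5": 35.0,   # pubic ramus
    "S3E1": 60.0,   # ischial seat
    "S3E6": 40.0,   # posterior proximal
    "S4E2": 35.0,   # lateral mid
    "S5E8": 38.0,   # lateral proximal
}

LATERAL_REGIONS = ("S4E2", "S5E8")

DISTAL, SCARPA = "S5E3", "S1E2"
PUBIC, ISCHIAL = "S2E5", "S3E1"


# --- membership families over normalized pressure (% above threshold) ------

def sensitive_family() -> dict[str, MF]:
    """Pressure-sensitive regions (e.g. distal-end): 'normal' sits at the
    threshold; 62 kPa at threshold 40 (x = +55) -> high 0.25, very_high 0.75."""
    return {
        "low": MF.shoulder_left("low", -50.0, -25.0),
        "normal": MF.trapezoid("normal", -50.0, -25.0, 0.0, 20.0),
        "high": MF.trapezoid("high", 0.0, 20.0, 40.0, 60.0),
        "very_high": MF.shoulder_right("very_high", 40.0, 60.0),
    }


def tolerant_family() -> dict[str, MF]:
    """Pressure-tolerant regions (e.g. Scarpa's triangle): comfortable
    pressure lies well below the tolerance threshold; 62 kPa at threshold 80
    (x = -22.5) -> normal 0.75, high 0.25."""
    return {
        "low": MF.shoulder_left("low", -80.0, -50.0),
        "normal": MF.trapezoid("normal", -80.0, -50.0, -30.0, 0.0),
        "high": MF.trapezoid("high", -30.0, 0.0, 20.0, 40.0),
        "very_high": MF.shoulder_right("very_high", 20.0, 40.0),
    }


def uniformity_family() -> dict[str, MF]:
    """Two-set family over the coefficient of variation of the lateral-side
    region pressures; crossover at CV = 0.25."""
    return {
        "uniform": MF.shoulder_left("uniform", 0.15, 0.35),
        "nonuniform": MF.shoulder_right("nonuniform", 0.15, 0.35),
    }


def output_family() -> dict[str, MF]:
    """Rectification-magnitude sets over pad/wall thickness (mm)."""
    return {
        "small": MF.triangle("small", 4.0, 9.0, 14.0),
        "medium": MF.triangle("medium", 14.0, 19.0, 24.0),
        "large": MF.triangle("large", 24.0, 29.0, 34.0),
        "very_large": MF.shoulder_right("very_large", 30.0, 36.0),
    }


# --- rule base (static rules, quadrilateral socket) -------------------------

HIGH = ("high", "very_high")  # 'high pressure' atoms cover both upper sets


def default_rules() -> tuple[Rule, ...]:
    return (
        # Rule set I — the distal-end must not carry high pressure
        Rule("I.1", (Term(DISTAL, HIGH), Term(SCARPA, ("low",))),
             zone="anterior_scarpa", magnitude="large"),
        Rule("I.2", (Term(DISTAL, ("normal",)), Term(SCARPA, ("low",))),
             zone="anterior_scarpa", magnitude="medium"),
        Rule("I.3", (Term(DISTAL, ("low",)), Term(SCARPA, ("low",))),
             zone="anterior_scarpa", magnitude="small"),
        Rule("I.4", (Term(DISTAL, HIGH), Term(SCARPA, ("low",), negated=True)),
             flag=SOCKET_TOO_SHORT),
        # Rule set II — keep the ischium seated on the ischial seat
        Rule("II.1", (Term(PUBIC, HIGH), Term(ISCHIAL, ("low",))),
             zone="anterior_wall", magnitude="large"),
        Rule("II.2", (Term(PUBIC, HIGH), Term(ISCHIAL, ("normal",))),
             zone="anterior_wall", magnitude="medium"),
        # Rule set III — proper tightness along the lateral wall
        Rule("III.1", (Term("lateral_uniformity", ("nonuniform",)),
                       Term("lateral_side", ("low",))),
             zone="lateral_wall", magnitude="large"),
        Rule("III.2", (Term("lateral_uniformity", ("nonuniform",)),
                       Term("lateral_side", ("normal",))),
             zone="lateral_wall", magnitude="medium"),
    )


def default_zones() -> dict[str, ZoneSpec]:
    return {
        "anterior_scarpa": ZoneSpec("anterior_scarpa", 280.0, 340.0, 30.0, 110.0,
                                    r_ref=55.0, action_type="pad"),
        "anterior_wall": ZoneSpec("anterior_wall", 250.0, 340.0, 0.0, 120.0,
                                  r_ref=58.0, action_type="pad"),
        "lateral_wall": ZoneSpec("lateral_wall", 330.0, 30.0, 20.0, 180.0,
                                 r_ref=52.0, action_type="pad"),
    }


def default_config(regions: list[AnatomicalRegion] | None = None) -> FuzzySystemConfig:
    """The full default inference system for the default region layout."""
    regions = DEFAULT_REGIONS if regions is None else regions
    input_mfs = {}
    for region in regions:
        fam = sensitive_family() if region.tolerance_class == "sensitive" else tolerant_family()
        input_mfs[region.region_id] = fam
    input_mfs["lateral_side"] = tolerant_family()
    input_mfs["lateral_uniformity"] = uniformity_family()
    return FuzzySystemConfig(
        input_mfs=input_mfs,
        output_mfs=output_family(),
        rules=default_rules(),
        zones=default_zones(),
        output_domain=(0.0, 36.0),
        defuzz_step=0.1,
        lateral_regions=LATERAL_REGIONS,
    )


def default_thresholds(regions: list[AnatomicalRegion] | None = None) -> dict[str, float]:
    """Per-region thresholds carried by the default region table."""
    regions = DEFAULT_REGIONS if regions is None else regions
    return {r.region_id: r.threshold for r in regions}
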