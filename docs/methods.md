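# Methods

This note documents the models, conventions, defaults and known limits of
`socketfit`, in the order the pipeline uses them.

## Socket geometry and coordinates

A socket is a single triangle-mesh shell, open at the proximal brim and
capped at the distal end. Positions on the wall use a cylindrical frame
anchored at the highest point of the proximal *lateral* brim:

* **h** — depth below the brim reference (mm, ≥ 0, growing distally);
* **θ** — degrees, **clockwise when viewed from the open (proximal) end
  looking distally**, 0° at the brim reference, normalized to [0, 360);
* **r** — distance from the socket axis (mm).

Region files (`z_min, z_max, theta_min, theta_max`) use exactly this
convention; regions may wrap through 0° (`theta_min > theta_max`). For
synthetic sockets the frame is the generation frame; imported STLs have no
canonical axis, so the frame (axis origin, direction, θ = 0 direction) must
be supplied in configuration. Lengths are mm throughout (STL is unitless),
pressures kPa.

The synthetic generator produces a tapered shell whose cross-sections are
ellipses shrinking from brim semi-axes (default 70 × 55 mm) to distal
semi-axes (25 × 22 mm) over 300 mm with taper exponent 1.5 — adult
transfemoral check-socket proportions, a stand-in for a scanned socket,
not a replica of any specific geometry. The default resolution (96 vertices
per ring, 60 rings) keeps every operation in this package well under a
second; refinement tests show the enclosed volume is stable to < 0.5% under
doubling. The *loose* variant scales every vertex radially about the axis
by √(1 + f), which multiplies each cross-sectional area exactly by (1 + f)
(default f = 0.05) uniformly along the full length, cannot self-intersect,
and leaves topology unchanged. Interior volume is measured by fan-capping
the open brim loop and applying the divergence theorem.

## Region aggregation and normalization

Pressure samples (sensor pads, or a sampled field) falling inside a region
are pooled and averaged — one mean per region, invariant under permutation
and batch splitting. A region with no samples reports 0 kPa with an
explicit no-contact flag rather than missing data: non-contacting sensors
are a physical outcome (they normalize far below threshold and therefore
read *low*), not a data error. Region bounds are half-open on their max
edges so disjoint regions partition the wall.

Normalization is relative: x = 100·(p − T)/T percent above the region
threshold T (an absolute variant 100·(p − T)/p_ref is available). The
relative form is scale-free across regions whose comfortable pressures
differ by an order of magnitude.

Thresholds are calibrated from a benchmark comfortable socket as
`T_i = max(p_i, floor) · scale_i`, floor 1 kPa. The scale is
per-tolerance-class by default: **sensitive 1.0** (nominal pressure sits at
threshold, x = 0, middle of the *normal* label's reach) and **tolerant
5/3** (nominal normalizes to −40%, the centre of the tolerant *normal*
plateau — tolerant regions tolerate well above their comfortable load).
A global variant factor multiplies all thresholds to emulate stricter or
laxer tolerance settings; raising it weakens every normalized signal and
the rules respond with smaller rectification.

## Membership functions

Input families are piecewise-linear trapezoids/shoulders over normalized
pressure, one family per tolerance class; adjacent labels are complementary
on their transitions (degrees sum to 1). Exact breakpoints for such
families are not published anywhere we know of; ours are **calibrated to
the two standard worked readings** and must be treated as configuration:

* sensitive (e.g. distal-end, threshold 40 kPa): low ≤ −50…−25, normal
  −50…−25…0…20, high 0…20…40…60, very_high 40…60 ≤. A 62 kPa reading
  (x = +55) gives high 0.25 / very_high 0.75.
* tolerant (e.g. Scarpa's triangle, threshold 80 kPa): the same shape
  shifted down by 80 points (low ≤ −80…−50, …, very_high 20…40 ≤).
  62 kPa (x = −22.5) gives normal 0.75 / high 0.25.

Out-of-domain inputs clamp to the nearest shoulder. The output family over
pad/wall thickness (domain 0–36 mm, centroid grid 0.1 mm) uses symmetric
triangles centred at **9 / 19 / 29 mm** for small/medium/large (plus a
very_large shoulder at 30–36 mm), so a single fully-fired rule defuzzifies
to exactly those magnitudes — the low/medium/high rectification variants
the closed loop realizes.

## Rule base and inference

Static rules only (dynamic gait-phase rules are out of scope). Three sets:

* **I (distal-end)** — high/normal/low distal pressure with low Scarpa
  pressure ⇒ large/medium/small anterior volume reduction at Scarpa's
  area; high distal *without* low Scarpa ⇒ categorical *socket too short*.
* **II (ischial seat)** — high pubic-ramus pressure with low/normal
  ischial-seat pressure ⇒ large/medium anterior-wall pad.
* **III (lateral wall)** — non-uniform lateral pressure with low/medium
  lateral level ⇒ large/medium lateral pad. "Not uniform" is
  operationalized as the coefficient of variation of the lateral region
  means, fuzzified with a two-set {uniform, nonuniform} family crossing at
  CV = 0.25; no standard uniformity statistic exists for this rule, so the
  CV choice is a documented design decision.

A "high pressure" atom is the max of the *high* and *very_high* degrees:
a reading far above the high support must keep firing the high-pressure
rules, otherwise the prescribed magnitude would fall again at extreme
pressures and monotonicity (more distal pressure ⇒ never less anterior
rectification) would break. Negation is the standard complement 1 − μ.
Operators are min (AND), min (implication), max (aggregation), centroid
defuzzification — the classic Mamdani controller family; the categorical
flag is raised when its best firing strength exceeds 0.5. In the crisp 0/1
limit the engine reduces exactly to propositional logic (verified
exhaustively in the tests).

## Mesh rectification

The wall splits into control region H (between θ_AS and θ_LE clockwise,
inside a height band; closed at the start angle, open at the end — an
arbitrary, documented convention) and fixed region F; F never moves. Each
H vertex moves *inward* along its outward unit vertex normal (rectification
is inner-volume reduction). Besides the constant-displacement mode, the
antero-lateral blend evaluates, in the clockwise offset u ∈ [0, Δθ] from
θ_AS (Δθ = clockwise extent to θ_LE; the printed |θ_AS − θ_LE| under the
no-wrap convention):

1. logistic rise 0 → m_A on [0, 0.1·Δθ];
2. plateau m_A;
3. logistic transition m_A → m_L on the interval θ_AL ± Δθ/2;
4. plateau m_L;
5. logistic fall m_L → 0 on [0.9·Δθ, Δθ];

then scales by h/h_max (h_max = maximum depth found in H), so displacement
grows toward the distal end of the control region (an inverted "taper
toward proximal" reading is available by overriding the height band).

Numerical choices: logistic steepness defaults to k = 2·ln(99)/width — the
sigmoid covers 98% of its range inside its interval, leaving a 1% residual
at each join — with the midpoint at the interval centre; both are
overridable per spec. The nominal middle-transition interval θ_AL ± Δθ/2
*always* reaches into the 10% edge zones, so it is clamped between them and
its k and midpoint follow the clamped interval; this keeps the profile
continuous to within the 1% residual for any θ_AL placement, and a warning
is raised only if clamping collapses the transition entirely. Displacements
that would reach the socket axis raise an error; faces whose normals flip
after displacement trigger a self-intersection warning (detection only, no
repair). Topology is never altered.

Zone-to-blend mapping: anterior-Scarpa and anterior-wall actions drive m_A,
lateral-wall actions m_L (max over contributors), applied in one pass with
the configured template (default θ_AS = 250°, θ_AL = 335°, θ_LE = 60°,
heights 0–180 mm).

## Donning surrogate

The surrogate replaces a finite-element contact simulation with the
simplest model that reproduces the qualitative behaviour being emulated;
it is emphatically **not** contact mechanics, and its absolute pressures
carry no physical authority. The stump slides distally by
`slide = max(0, slide_gain·A% − relief·Σ w_z·t_z)` mm (A% = percent area
increase, t_z = per-zone plateau thickening, w = 0.5 — the blend and height
scaling mean the average thickening is roughly half the plateau). Then

* distal-end: p = baseline + transfer·slide;
* every other region: p = max(0, baseline + stiffness·(Σ c_z·t_z − slack)),
  slack = slack_coeff·slide.

Tying proximal slack to *slide* (not to area directly) encodes the causal
chain — a loose socket unloads proximal regions because the stump settles
distally — and means that with slide_gain = 0 a loose socket produces no
pressure anomaly and hence no rectification. Defaults (transfer = stiffness
= 8 kPa/mm, slide_gain = 1.2 mm/%, slack_coeff = 0.8, relief = 0.5,
couplings 0.5 to a region's own wall zone and 0.1–0.4 across) were chosen
once so that a 5% loose socket produces an unambiguous loose signature
(distal-end 88 kPa ≫ its 40 kPa threshold; Scarpa 9.6 kPa, deep in *low*)
and a clamped-to-zero region appears near the brim (the non-contacting
sensor case). Noise is off by default — the emulated reference simulation
is deterministic — with optional seeded Gaussian noise for robustness
experiments.

The closed loop (nominal → calibrate → loose → infer → rectify →
re-simulate) runs three threshold variant factors (1.0 / 2.5 / 5.0). These
land the loose distal signal in the very-high, normal and low label ranges
respectively, so rules I.1/I.2/I.3 dominate in turn and the realized
magnitudes are 29 / 19 / 9 mm. Fit quality is summarized as each region's
normalized excess over the *base* (factor 1) thresholds; the medium variant
minimizes the maximum excess — the distal-vs-proximal trade-off the rule
base is designed around.

## What the synthetic setup does and does not show

The generator and surrogate exercise every code path deterministically and
reproduce the *orderings* a loose and a rectified socket exhibit (distal
pressure up with looseness, down with rectification; proximal pressures the
reverse; non-contacting proximal sensors). Passing tests therefore
demonstrate internal consistency and faithfulness to those mechanisms —
not predictive accuracy on real stump–socket interfaces: real pressure
fields are patient-specific, non-axisymmetric, gait-dependent and include
shear, none of which the surrogate models. Membership breakpoints, zone
angles and surrogate coefficients are configuration to be re-calibrated
per patient and per socket style (the default rule base targets a
quadrilateral transfemoral socket).

## Other limitations

* No mesh repair or remeshing; imported STLs are assumed manifold enough
  for sectioning and normals.
* Self-intersection after extreme displacement is detected (normal flips),
  not repaired.
* Only the Mamdani min/max/min operator family and centroid
  defuzzification are implemented; the operator fields exist in the config
  so alternatives fail loudly rather than silently.
* Eq-style redundancy: an action's r coordinate is reported as the zone
  centre's configured reference radius — once the zone is fixed on the
  wall, r carries no independent information.
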