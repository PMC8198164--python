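# socketfit

Decision support for **transfemoral prosthetic socket rectification**.
`socketfit` turns region-averaged stump–socket interface pressures (kPa)
into concrete rectification actions — *where* to thicken the inner socket
wall, *by how much* (mm), and *how* (silicone pad or heat-gun deformation) —
and applies those actions to a 3D socket model stored as an STL triangle
mesh. A built-in donning-pressure surrogate closes the loop offline, so the
whole pipeline (nominal socket → loose socket → inference → rectified
socket → re-evaluation) runs without any FEA or sensor hardware.

Intended users: prosthetics researchers and engineers prototyping
sensor-driven socket-fitting workflows.

## The method

**Fuzzy inference.** Each anatomical region *i* of the socket wall
(distal-end, Scarpa's triangle, ischial seat, …) carries a pressure
tolerance threshold *Tᵢ*. A mean regional pressure *p* is normalized to
*x = 100·(p − Tᵢ)/Tᵢ* (percent above threshold) and fuzzified through
membership functions μᵢ(x) for the linguistic labels *low / normal / high /
very high*. A rule base of prosthetist heuristics, e.g.

```
IF distal_end IS high AND scarpa_triangle IS low
THEN anterior_scarpa IS large          # loose socket: stump slides distally
IF distal_end IS high AND NOT (scarpa_triangle IS low)
THEN socket_too_short                  # categorical: replace the socket
```

is evaluated Mamdani-style (min for AND, 1 − μ for NOT, min implication,
max aggregation) and the aggregated thickness set for each rectification
zone is defuzzified by its centroid into a crisp magnitude in mm. Each
action is the triple *R = {μ(x), (r, θ), {pad, heatgun}}*: magnitude,
location in socket polar coordinates, and action type.

**Mesh rectification.** The socket wall is parameterized by (h, θ, r):
depth below the proximal-lateral brim reference, clockwise angle (0° at the
reference, viewed from the open end looking distally), and radius. Vertices
inside the control region H (between θ_AS and θ_LE, within a height band)
move inward along their vertex normals by a blended coefficient:
logistic rises/falls over the first and last 10% of the angular extent
Δθ_max, plateaus at the anterior and lateral magnitudes m_A and m_L with a
logistic transition between them centred near θ_AL, all scaled by h/h_max.
The fixed region F never moves; no PDE or optimization is involved.

**Surrogate.** A linear spring-foundation model maps socket state
(cross-sectional area increase, per-zone wall thickening) to per-region
pressures, reproducing the qualitative loose-socket signature (high
distal-end, unloaded Scarpa's triangle) and the rectification trade-off
(distal off-loading vs rising proximal pressures). See `docs/methods.md`.

## Worked example

```python
from socketfit import *
from socketfit.defaults import default_config, default_thresholds

cfg, thr = default_config(), default_thresholds()

# the classic worked reading: 62 kPa means different things in different regions
print(fuzzify_pressure(62.0, "S5E3", cfg, thr))  # distal-end (sensitive)
# {'low': 0.0, 'normal': 0.0, 'high': 0.25, 'very_high': 0.75}
print(fuzzify_pressure(62.0, "S1E2", cfg, thr))  # Scarpa's triangle (tolerant)
# {'low': 0.0, 'normal': 0.75, 'high': 0.25, 'very_high': 0.0}

# closed loop: the three threshold variants realize distinct rectifications
report = closed_loop_demo()
for name, v in report["variants"].items():
    print(name, v["thickening"], round(v["max_excess_pct"], 1))
# high {'anterior': 29.0} 114.7
# medium {'anterior': 18.999999999999996} 48.0
# low {'anterior': 9.000000000000002} 75.0
print(report["tradeoff"]["best_variant"])   # medium
```

A 62 kPa reading is *mostly very high* at the pressure-sensitive distal-end
but *mostly normal* at pressure-tolerant Scarpa's triangle. In the closed
loop, a socket loosened by 5% cross-sectional area drives the distal-end
pressure far above threshold; depending on threshold tuning the engine
prescribes a 9, 19 or 29 mm antero-lateral volume reduction, and the medium
variant best balances distal off-loading against proximal overload (lowest
maximum normalized excess).

The same pipeline is scriptable from the shell:

```bash
socketfit synth -o socket.stl
socketfit loosen socket.stl --area-increase 0.05 -o loose.stl
socketfit demo --out-dir demo_out --seed 0
```

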