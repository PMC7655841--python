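# Methods

This note documents the models behind each `calcmech` module, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that matter.

## Compression reduction

**Model.** A micro-pillar of top diameter D₁, bottom diameter D₂ and
height h (all µm), compressed by a flat punch, sinks elastically into its
substrate. For a slightly tapered pillar the combined column-plus-substrate
compliance gives the normalized engineering measures

    εₙ = δ/h,   σₙ = (4/(π D₁ D₂) + (1 − ν²)/(D₂ h)) · F,

with ν the Poisson ratio of calcite (default 0.3, the directional
average). Forces are ingested in mN and depths in nm (instrument-native),
converted to SI internally, and stresses reported in GPa. Two limits
anchor the formula: as h → ∞ the substrate term vanishes and
σₙ → 4F/(π D₁D₂); for an untapered pillar D₁ = D₂ it reduces to the
ordinary column-plus-half-space result. The yield and maximum strengths
use the *top-section* stress measures σ_Y = 4F_Y/(πD₁²) and
σ_max = 4F_max/(πD₁²), which for the nominal pillar (D₁ = 2 µm, aspect
ratio 3, taper 2.5°) sit ≈ 1.9 % above the normalized measure at the same
force. The two measures are both standard and are reported as such; this
small systematic difference is inherent to the dual convention, and is
also why a measured elastic limit ε_e need not equal σ_Y/E exactly.

**Modulus.** E is the least-squares slope over the 50–95 % stress window
of the *elastic portion* of the loading curve. The elastic portion is
located first with a provisional fit over the surely-elastic 25–50 %
range; its end is the first point whose median-smoothed stress falls more
than 2 % below the provisional line for three consecutive samples.
Windowing on the peak stress instead would pull post-yield points of
hardening curves into the regression.

**Yield.** The onset of nonlinearity is the last loading point consistent
with the elastic line through the origin: stress is smoothed with a
5-point running median, and a point "deviates" when it falls below the
line by more than the offset tolerance (default 2 %, relative), persisting
for three samples. The relative deviation's denominator is floored at
half the peak stress so transducer noise at the foot of the curve cannot
fire a spurious detection. For gradually hardening knees the estimate is
refined by intersecting the elastic line with a local fit of the clearly
plastic branch; the refinement is accepted only within 5 % of the
first-deviation strain, so burst-type curves — where the first deviating
point is the burst itself — keep the last elastic point as the onset. On
noise-free data the detector converges to the exact knee as the tolerance
shrinks. A curve that never deviates returns a no-yield flag, not an
exception.

**Failure.** ε_f is the strain just before an abrupt *terminal* load
drop: a one-step relative force drop above 50 % from a level above half
the peak force, after which the load never recovers past 30 % of the
peak. The terminal condition distinguishes fracture from a yield burst
followed by reloading to a flow plateau.

**Burst and flow.** A displacement burst is a per-step strain increment
larger than 5× the median loading increment. The flow strength σ_f is the
mean stress over the longest contiguous post-burst region whose slope
magnitude stays below 0.1·E. The local slope is estimated with a
Savitzky–Golay first derivative over a 41-point window: with 0.01 GPa
stress noise on a 10⁻⁴ strain grid, a point-wise difference quotient has
~10² GPa of slope noise and would never find the plateau.

**Cohorts.** Per-group mean ± sd for each property, and two-sample
*t* tests (pooled variance by default, Welch optional) between groups at
the 0.05 level.

## Weibull statistics

Strengths are modelled by f(σ) = 1 − exp(−(σ/σ_Y0)^m). The default
estimator regresses ln(−ln(1 − f_i)) on ln σ_i with median-rank plotting
positions f_i = (i − 0.5)/n (i/(n+1) available), matching the straight-line
Weibull-plot presentation and providing an R². The maximum-likelihood
estimator solves the profiled score equation in m by bracketed
root-finding (the score is monotone in m), with the scale in closed form.
Standard errors come from a seeded nonparametric bootstrap (default 2000
resamples); the provenance of published "±" values on Weibull moduli is
rarely stated, and the bootstrap is a defensible default. Degenerate
(all-equal) samples raise a fit error. Both estimators are
scale-equivariant: rescaling the sample rescales σ_Y0 and leaves m
unchanged.

## Crystallography

Miller–Bravais indices are interpreted in the hexagonal *structural* cell
of calcite, default a = 4.99 Å, c = 17.06 Å (configurable); plane normals
go through the reciprocal basis and directions through the direct basis,
with the four-index direction [uvtw] mapped to three-index [u−t, v−t, w].
The catalog holds the twelve classical deformation systems: 3 e-twin
systems (unidirectional, positive sense), 3 r-slip and 6 f-slip systems
(bidirectional); each is validated against the zone condition
hu + kv + it + lw = 0 and the Cartesian orthogonality of direction and
normal (10⁻⁸).

Schmid factors are signed, m = (n̂·p̂)(n̂·d̂); under compression the shear
resolved along +d̂ has the sign of −m, which decides whether a
unidirectional twin is activated and in which sense a slip system
operates. Under c-axis compression the three r systems are degenerate at
|m| = 0.499957 — within 4·10⁻⁶ of the ideal-orientation value reported
for this loading — and operate in the negative sense, while the e twins
see shear in their forbidden sense and stay dormant. The value depends on
the cell ratio c/a (it varies smoothly, reaching 0.5 only at the exact
45°/45° geometry), so the cell parameters are explicit and configurable
rather than baked in.

## Wing-crack strength model

The compressive strength of a crystal containing sliding elliptical flaws
(half-length a, spacing L, inclination θ from the transverse plane) is

    σ_y = (2π/11)^¼ · √L · σ_Y,c √(πa) / (20 β(θ) a),

taken literally, including the interaction constants 11 and 20. The
expression is dimensionless in length (only √(L/a) enters), linear in the
matrix strength σ_Y,c, and scales exactly as √L — so strength *ratios*
between flaw configurations are parameter-free. The orientation factor

    β(θ; μ) = max(sin θ cos θ − μ cos²θ, β_floor)

is the resolved frictional-sliding form with friction μ (default 0.3) and
a positive floor (default 0.1) keeping the model finite for flaws lying
in the transverse plane, which cannot slide; β is injectable so any other
closed form can be dropped in. Because σ_y ∝ 1/β, a single global β
multiplier can be calibrated so the prediction at a reference
configuration matches an anchor strength; anchoring σ_y(L = 32 nm, θ = 0)
at the 0.96 GPa strength of defect-free calcite gives a 32 → 10 nm
strength reduction of 0.96·(1 − √(10/32)) ≈ 0.42 GPa. Absolute,
uncalibrated values depend on the unknown true β and should not be
over-interpreted; the θ trend (strength falling as θ grows through
30–50°) and the √L scaling are the robust content.

The stress-concentration anisotropy of an elliptical flaw is quantified
with the Inglis hole factor k_t = 1 + 2·(axis ratio) at each tip; the
long-axis/short-axis ratio is 1 for a circle and 2.5 for the measured
10 × 5 nm defect geometry. This is a deliberate simplification standing
in for a full stress-intensity analysis; it is used only for the
more-than-doubled anisotropy statement, not for absolute toughness.

## Strengthening

The flow-stress increment of the defect-containing crystal is recovered
from the hardness contrast via H = H₀ + C·Δσ_Y with the constraint
coefficient C explicit everywhere (default 3, the classical Tabor-style
hardness-to-flow-stress factor). The predicted intrinsic strength is the
defect-free yield strength plus the increment; when it exceeds the
measured strength the "fracture before yield" flag fires — the
interpretation being that dislocation motion is so obstructed that
cracking intervenes first. Negative increments (softening) are permitted
but flagged.

## Defect geometry

Contours (≥ 5 points, nm) are fitted by direct least-squares conic
fitting constrained to an ellipse (the numerically stable Halir–Flusser
scheme, via scikit-image), with orientation reported in (−90°, 90°] from
the transverse image axis so θ = 0 means a defect lying flat. Population
summaries give means ± sd of the semi-axes and orientation and a mean
radial contour (contours re-centred on their fitted centres, radius
interpolated on a common 64-angle grid, averaged). Nearest-neighbour
spacing is centre-to-centre by default (edge-to-edge, subtracting mean
radii, as an option; the operational definition of published spacings is
rarely stated). Per-zone statistics restrict neighbours to the same zone,
isolating each zone's lattice spacing from cross-boundary pairs. Density
classing labels defects high/low by local count within 50 nm, thresholded
at the field median — adequate when the classes are balanced, but when
one class dominates the count the median falls inside it and the minority
class is recovered cleanly while the majority splits; the zone labels
carried by the synthetic generator are the ground truth for testing. The
orientation profile bins mean |θ| against the shortest distance to the
boundary polyline (50 nm bins) with a monotonicity diagnostic.

## Synthetic data

The curve generator renders piecewise constitutive templates and inverts
them through the compliance relation to instrument-native force/depth,
with additive Gaussian stress noise (default sd 0.01 GPa; instrument
noise is not characterized in published work, and 0.01 GPa is ~1 % of the
strength scale) on a 10⁻⁴ strain grid, timestamps assuming the 10 nm/s
displacement rate:

* biogenic class — linear elasticity to σ_Y, linear hardening to fracture
  at ε_f, terminal collapse; defaults E = 34.4 GPa, σ_Y = 1.16 GPa,
  ε_f = 0.074, hardening chosen so the failure stress equals the measured
  σ_max = 1.32 GPa;
* geological class — linear elasticity to σ_Y, a single-step displacement
  burst with load drop to 0.75 σ_f, linear reload at the elastic slope,
  then steady flow; defaults E = 47.9 GPa, σ_Y = 0.96 GPa, σ_f = 0.47 GPa.
  The burst size Δε is not a tabulated cohort value; 0.01 strain matches
  the visual scale of the jump. The real burst involves tip retraction
  and re-approach; the jump-plus-reload rendering keeps depth monotone
  and preserves everything the reduction measures.

Cohort draws perturb the class means with the measured cohort standard
deviations (truncated to keep templates well-posed: ε_f above the elastic
limit, flow below yield). The generators are pure functions of
(spec, seed).

Strength samples are inverse-CDF Weibull draws. Defect fields place
ellipse centres on jittered square lattices (jitter sd 2 % of pitch)
inside alternating low/high-density bands (default period 400 nm,
spacings 32 and 10 nm), with semi-axes 5 × 2.5 nm (5 % scatter) and
inclination θ(d) = 40°·exp(−d/100 nm) ± 2° noise of random sign at
distance d from the x = 0 boundary — a law chosen to reproduce the
observed contrast (interior < 5°, near-boundary > 30°) since no
functional form is published. Contours are 32 points per ellipse with
0.1 nm radial noise.

**What the generators do not emulate:** thermal drift, frame compliance,
tip misalignment, load-controlled segments, the retraction transient of
real displacement bursts, non-elliptical or sharp-cornered defects, 3-D
defect shapes (sections only), and any correlation between defect density
and mechanical parameters. Passing round-trip tests therefore shows the
*reduction chain* is consistent and unbiased under the stated noise
model, not that it is robust to every instrument artefact.

## Problem sizes and numerics

Round-trip tests use single curves (~10³ samples) and cohorts of 25–100
pillars; Weibull recovery uses n = 10⁴ single fits and 200 replicates at
the cohort size n = 25; defect fields hold ~4·10³ defects on a
1000 × 800 nm domain. These sizes put Monte-Carlo error well below the
asserted tolerances while keeping the full suite under a minute of
compute. Ties in Schmid ranking are grouped at 10⁻⁹; symmetry
degeneracies hold to 10⁻¹²; ellipse fits of exact contours recover
parameters to 10⁻⁸. Seeds are fixed everywhere randomness enters.

## Known limitations

* The true orientation factor β(θ) and the friction coefficient behind
  published strength maps are not available; only calibrated strength
  *differences* and qualitative θ trends are claimed.
* The constraint coefficient C and the hardness values behind the
  0.36 GPa strengthening increment are inputs, not derived quantities.
* The Schmid analysis is geometric: no critical resolved shear stresses,
  dislocation dynamics or twin-boundary energetics.
* Yield detection on real data depends on the offset tolerance; the 2 %
  default is this package's choice of an operational criterion for "onset
  of nonlinearity", which published reductions typically leave unstated.
  Both the tolerance and the window are exposed.
* ε_f is reported at the terminal load drop; the strain at peak load is
  also available (`strain_at_peak`) since conventions differ.
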