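# calcmech

Micromechanics of biogenic calcite: a Python library for reducing
micro-pillar compression experiments on single-crystal calcite (such as the
prisms of bivalve shells), analysing the statistics and crystallography of
their deformation, and modelling how nanoscopic intracrystalline defects set
their compressive strength.

Biogenic calcite crystals host dispersed nanoscopic organic inclusions
("intracrystalline defects", flattened ellipsoids roughly 10 × 5 nm).
These defects pin dislocations — suppressing the rhombohedral slip that
pure geological calcite deforms by — and simultaneously act as a
population of pre-existing flaws that nucleate and steer micro-cracks.
`calcmech` implements the quantitative chain that connects those two roles
to measurable numbers:

* **Compression reduction** — force–depth records (mN, nm) from flat-punch
  micro-pillar compression are converted to normalized engineering stress
  and strain with a Sneddon-type substrate-compliance correction for a
  slightly tapered pillar,

  σₙ = (4/(π D₁D₂) + (1 − ν²)/(D₂h)) F,  εₙ = δ/h,

  and reduced to E, σ_Y = 4F_Y/(πD₁²), σ_max = 4F_max/(πD₁²), ε_e, ε_f,
  and — for curves with a displacement burst at yield — the burst size Δε
  and flow plateau σ_f. Cohorts are compared with mean ± sd and two-sample
  *t* tests.
* **Weibull statistics** — two-parameter fits of
  f = 1 − exp(−(σ_Y/σ_Y0)^m), by Weibull-plot regression or maximum
  likelihood, with bootstrap uncertainties.
* **Crystallography** — the twelve twin/slip systems of calcite
  (e {-1018}<40-41>⁺, r {10-14}<-2021>±, f {-1012}<2-201>±) in
  Miller–Bravais indices, Cartesian geometry for the hexagonal structural
  cell, and signed Schmid factors m = cosφ·cosλ with twinning-sense
  bookkeeping.
* **Wing-crack strength model** — the closed-form compressive strength of a
  crystal with sliding elliptical flaws of half-length a, spacing L and
  inclination θ,

  σ_y = (2π/11)^¼ · √L · σ_Y,c √(πa) / (20 β(θ) a),

  with an injectable, calibratable orientation factor β(θ; μ), plus the
  Inglis stress-concentration anisotropy of an elliptical flaw.
* **Strengthening** — the precipitation-strengthening increment
  Δσ_Y = (H − H₀)/C from a hardness contrast, and the predicted intrinsic
  strength of the defect-containing crystal.
* **Defect geometry** — ellipse fits of digitized defect contours,
  population summaries with mean radial contours, nearest-neighbour spacing
  (per density zone), and the inclination-versus-distance-to-boundary
  profile.
* **Synthetic data** — seeded generators for both curve classes, Weibull
  strength samples and banded defect fields, so the whole chain is testable
  without instrument data.

## Worked example

Ranking calcite's deformation systems for compression along the c axis
(`examples/schmid_analysis.py`):

```
family      plane  direction         sense  schmid_factor   abs_m resolved_sense  activated
     r (1 0 -1 4) [-2 0 2 1] bidirectional        0.49996 0.49996       negative       True
     r (-1 1 0 4) [2 -2 0 1] bidirectional        0.49996 0.49996       negative       True
     r (0 -1 1 4) [0 2 -2 1] bidirectional        0.49996 0.49996       negative       True
     e (-1 0 1 8) [4 0 -4 1]      positive        0.39683 0.39683       negative      False
     ...
```

All three r-slip variants reach the near-ideal Schmid factor 0.49996 and
are activated in the negative sense, while the e twins see resolved shear
in their forbidden sense and stay dormant — c-axis compression of calcite
deforms by rhombohedral slip on symmetry-equivalent systems, which is why
compressed pillars keep circular cross-sections.

Calibrated wing-crack strength (`examples/wing_crack_strength_map.py`):

```
sigma_y(L = 32 nm) = 0.960 GPa   (calibration anchor)
sigma_y(L = 10 nm) = 0.537 GPa
reduction = 0.423 GPa
```

With β scaled so the nominal defect configuration (spacing 32 nm) matches
the 0.96 GPa compressive strength of defect-free calcite, densifying the
defects to a 10 nm spacing costs ≈ 0.42 GPa of strength — the model's
√L scaling makes this ratio parameter-free, and it is why micro-cracks
start in the high-density defect zones.

The other scripts in `examples/` demonstrate cohort reduction of synthetic
compression curves, Weibull analysis, the strengthening chain and defect
field statistics, each printing the numbers it computes with a short
interpretation.

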