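"""Weibull analysis of yield-strength samples for the two calcite classes.

Draws 25 biogenic and 22 geological strengths from the fitted strength
distributions and re-estimates the Weibull modulus m and scale with both
the linearized (Weibull-plot) regression and maximum likelihood.  A
larger m means a narrower strength distribution: the biogenic calcite is
the more reliable material even though individual defects weaken it.
"""

from calcmech import fit_weibull, generate_strengths

COHORTS = {
    # material: (n, Weibull modulus, scale GPa)
    "biogenic": (25, 5.74, 1.25),
    "geological": (22, 2.24, 1.08),
}

for material, (n, shape, scale) in COHORTS.items():
    sample = generate_strengths(n, shape, scale, seed=42)
    for method in ("linearized", "mle"):
        fit = fit_weibull(sample, method=method, n_bootstrap=500, seed=1)
        extra = f" R^2={fit.r_squared:.4f}" if fit.r_squared is not None else ""
        print(
            f"{material:11s} {method:10s} m = {fit.shape:5.2f} +/- {fit.shape_se:.2f}"
            f"  scale = {fit.scale:.3f} +/- {fit.scale_se:.3f} GPa{extra}"
        )
print()
print(
    "m is the Weibull modulus (shape): the biogenic sample should recover"
    " ~5.7 vs ~2.2 for the geological one, i.e. far less strength scatter."
)
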