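"""Reduce a synthetic micro-pillar compression cohort to mechanical properties.

Generates 12 biogenic-type and 12 geological-type force-depth records at
the measured cohort statistics, reduces each to stress/strain with the
tapered-pillar compliance correction, extracts E, sigma_Y, sigma_max,
eps_e, eps_f (and sigma_f for the burst-type curves), and prints the
per-group means with two-sample t tests.
"""

import numpy as np

from calcmech import (
    draw_cohort_spec,
    generate_curve,
    nominal_pillar_geometry,
    reduce_curve,
    summarize_cohort,
)

rng = np.random.default_rng(0)
geometry = nominal_pillar_geometry()

summaries = []
for material, n in (("biogenic", 12), ("geological", 12)):
    for _ in range(n):
        spec = draw_cohort_spec(material, rng)
        record = generate_curve(spec, geometry)
        summaries.append(reduce_curve(record, geometry, label=material))

group_stats, tests = summarize_cohort(summaries)
print("Per-group mean +/- sd of the reduced properties (GPa / strain):")
print(group_stats.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("Two-sample t tests between material classes:")
print(tests.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print(
    "The biogenic class should show the higher yield strength and a"
    " hardening-to-fracture response; the geological class yields by a"
    " displacement burst and flows near its plateau strength."
)
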