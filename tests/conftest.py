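import numpy as np
import pandas as pd
import pytest

from calcmech import PillarGeometry, StressStrainCurve, nominal_pillar_geometry


@pytest.fixture
def geometry() -> PillarGeometry:
    return nominal_pillar_geometry()


def curve_from_stress(strain, stress_gpa, geometry: PillarGeometry) -> StressStrainCurve:
    """Build a StressStrainCurve with a consistent raw force/depth record.

    Inverts the taper-corrected stress relation so tests can program
    stress-strain shapes directly while every downstream operation still
    sees a physically consistent force series.
    """
    strain = np.asarray(strain, dtype=float)
    stress = np.asarray(stress_gpa, dtype=float)
    force = stress / geometry.stress_coefficient_gpa_per_mn
    depth = strain * geometry.height_um * 1e3
    from calcmech import normalize_curve

    return normalize_curve(
        pd.DataFrame({"force_mN": force, "depth_nm": depth}), geometry
    )
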