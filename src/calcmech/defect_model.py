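"""Wing-crack strength model for a crystal containing nanoscopic sliding flaws.

Under compression, a pre-existing inclined flaw can slide against friction
and nucleate tensile "wing" cracks at its tips; coalescence of wing cracks
between neighbouring flaws sets the compressive fracture strength.  For a
population of elliptical flaws of half-length ``a`` (nm), centre-to-centre
spacing ``L`` (nm) and inclination ``theta`` (degrees from the transverse
plane, i.e. theta = 0 means the flaw's long axis is perpendicular to the
load), the predicted strength is

    sigma_y = (2*pi/11)**(1/4) * sqrt(L) * sigma_Yc * sqrt(pi*a) / (20 * beta(theta) * a)

where sigma_Yc is the compressive strength of the defect-free matrix and
beta(theta) encodes the resolved frictional sliding on the flaw.  Because
the expression scales exactly as sqrt(L/a), only ratios between flaw
configurations are parameter-free; an optional calibration rescales beta
globally so the prediction at a reference configuration matches a supplied
anchor strength.

The default orientation factor is the resolved-sliding form

    beta(theta; mu) = max(sin(theta)cos(theta) - mu*cos(theta)**2, beta_floor)

with friction coefficient mu (default 0.3) and a positive floor keeping the
model finite for near-transverse flaws that cannot slide.  The factor is
injectable: any callable theta_deg -> beta may replace it.

A simplified Inglis measure quantifies the stress-concentration anisotropy
of an elliptical flaw: k_t = 1 + 2*(axis ratio) at each tip, so flat flaws
concentrate stress much more strongly at the tips of their long axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

__all__ = [
    "DefectSpec",
    "MatrixSpec",
    "StrengthMap",
    "beta_orientation_factor",
    "wing_crack_strength",
    "calibrated_beta_scale",
    "strength_map",
    "elliptical_concentration_ratio",
]

#: Dimensionless prefactor of the wing-crack strength expression.
_PREFACTOR = (2.0 * np.pi / 11.0) ** 0.25

#: Region of the (L, theta) plane actually observed for the intracrystalline
#: defects: spacings from the dense zones (~10 nm) to the nominal lattice
#: (~32 nm), inclinations below ~5 degrees in the prism interior.
OBSERVED_L_NM = (10.0, 32.0)
OBSERVED_THETA_DEG = (0.0, 5.0)


@dataclass(frozen=True)
class DefectSpec:
    """Geometry and friction of one elliptical intracrystalline defect."""

    half_length_nm: float = 5.5
    height_nm: float = 5.0
    lateral_span_nm: float = 10.0
    inclination_deg: float = 0.0
    spacing_nm: float = 32.0
    friction_coefficient: float = 0.3

    def __post_init__(self) -> None:
        if self.half_length_nm <= 0:
            raise ValueError("half_length_nm must be positive")
        if self.spacing_nm <= 0:
            raise ValueError("spacing_nm must be positive")
        if not 0.0 <= self.inclination_deg <= 90.0:
            raise ValueError("inclination_deg must lie in [0, 90]")
        if self.friction_coefficient < 0:
            raise ValueError("friction_coefficient must be non-negative")


@dataclass(frozen=True)
class MatrixSpec:
    """Compressive strength of the defect-free (geological) matrix, GPa."""

    compressive_strength_gpa: float = 0.96

    def __post_init__(self) -> None:
        if self.compressive_strength_gpa <= 0:
            raise ValueError("compressive strength must be positive")


def beta_orientation_factor(
    theta_deg: float | np.ndarray,
    mu: float = 0.3,
    floor: float = 0.1,
) -> float | np.ndarray:
    """Resolved-sliding orientation factor beta(theta; mu), floored.

    theta is measured from the transverse plane (perpendicular to the
    load axis).  The sliding driving term sin*cos is opposed by friction
    mu*cos^2; where the net term is non-positive (near-transverse flaw,
    high friction) the positive ``floor`` applies.
    """
    theta = np.radians(theta_deg)
    if np.any((np.asarray(theta_deg) < 0) | (np.asarray(theta_deg) > 90)):
        raise ValueError("theta_deg must lie in [0, 90]")
    if floor <= 0:
        raise ValueError("floor must be positive to keep the model finite")
    raw = np.sin(theta) * np.cos(theta) - mu * np.cos(theta) ** 2
    out = np.maximum(raw, floor)
    return float(out) if np.isscalar(theta_deg) else out


BetaFunction = Callable[[float], float]


def wing_crack_strength(
    defect: DefectSpec,
    matrix: MatrixSpec,
    beta_function: BetaFunction | None = None,
    beta_scale: float = 1.0,
) -> float:
    """Predicted compressive fracture strength (GPa) of the flawed crystal.

    ``beta_function`` maps inclination (degrees) to beta; by default the
    resolved-sliding form with the defect's friction coefficient.
    ``beta_scale`` multiplies beta globally (used for calibration against
    an anchor strength; see :func:`calibrated_beta_scale`).
    """
    if beta_function is None:
        mu = defect.friction_coefficient

        def beta_function(theta_deg: float) -> float:
            return beta_orientation_factor(theta_deg, mu=mu)

    beta = beta_scale * beta_function(defect.inclination_deg)
    if beta <= 0:
        raise ValueError("beta(theta) must be positive; raise the floor")
    a = defect.half_length_nm
    length_ratio = np.sqrt(defect.spacing_nm / a)  # dimensionless sqrt(L/a)
    return float(
        _PREFACTOR
        * length_ratio
        * matrix.compressive_strength_gpa
        * np.sqrt(np.pi)
        / (20.0 * beta)
    )


def calibrated_beta_scale(
    defect: DefectSpec,
    matrix: MatrixSpec,
    anchor_strength_gpa: float,
    beta_function: BetaFunction | None = None,
) -> float:
    """Global beta multiplier making the prediction at ``defect`` equal the anchor.

    sigma_y is proportional to 1/beta, so the required multiplier is the
    ratio of the uncalibrated prediction to the anchor.
    """
    if anchor_strength_gpa <= 0:
        raise ValueError("anchor strength must be positive")
    uncalibrated = wing_crack_strength(defect, matrix, beta_function)
    return uncalibrated / anchor_strength_gpa


@dataclass(frozen=True)
class StrengthMap:
    """Strength predictions on an (L, theta) grid.

    ``strength_gpa[i, j]`` is the prediction at ``theta_deg[i]``,
    ``spacing_nm[j]``.  ``observed_box`` masks the grid cells inside the
    experimentally observed defect-configuration window.
    """

    spacing_nm: np.ndarray
    theta_deg: np.ndarray
    strength_gpa: np.ndarray
    observed_box: np.ndarray

    def to_dataframe(self):
        """Long-form DataFrame with columns L_nm, theta_deg, sigma_y_GPa, observed."""
        import pandas as pd

        tt, ll = np.meshgrid(self.theta_deg, self.spacing_nm, indexing="ij")
        return pd.DataFrame(
            {
                "L_nm": ll.ravel(),
                "theta_deg": tt.ravel(),
                "sigma_y_GPa": self.strength_gpa.ravel(),
                "observed": self.observed_box.ravel(),
            }
        )


def strength_map(
    spacing_nm: np.ndarray,
    theta_deg: np.ndarray,
    defect_template: DefectSpec | None = None,
    matrix: MatrixSpec | None = None,
    beta_function: BetaFunction | None = None,
    beta_scale: float = 1.0,
) -> StrengthMap:
    """Evaluate the wing-crack strength over a grid of spacings and inclinations."""
    spacing_nm = np.atleast_1d(np.asarray(spacing_nm, dtype=float))
    theta_deg = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    if spacing_nm.size == 0 or theta_deg.size == 0:
        raise ValueError("grids must be non-empty")
    if defect_template is None:
        defect_template = DefectSpec()
    if matrix is None:
        matrix = MatrixSpec()

    out = np.empty((theta_deg.size, spacing_nm.size))
    for i, theta in enumerate(theta_deg):
        for j, spacing in enumerate(spacing_nm):
            d = replace(defect_template, inclination_deg=float(theta), spacing_nm=float(spacing))
            out[i, j] = wing_crack_strength(d, matrix, beta_function, beta_scale)
    tt, ll = np.meshgrid(theta_deg, spacing_nm, indexing="ij")
    observed = (
        (ll >= OBSERVED_L_NM[0])
        & (ll <= OBSERVED_L_NM[1])
        & (tt >= OBSERVED_THETA_DEG[0])
        & (tt <= OBSERVED_THETA_DEG[1])
    )
    return StrengthMap(spacing_nm, theta_deg, out, observed)


def elliptical_concentration_ratio(lateral_span_nm: float, height_nm: float) -> float:
    """Long-axis vs short-axis Inglis stress-concentration ratio of an ellipse.

    For semi-axes a >= b, the tip of the long axis concentrates stress by
    k_t = 1 + 2 a/b under transverse tension and the short-axis tip by
    1 + 2 b/a; the returned ratio k_t(long)/k_t(short) is 1 for a circle
    and grows with flatness.  This is the simplified stand-in used to
    quantify why flat defects favour cracking along their long axes.
    """
    if lateral_span_nm <= 0 or height_nm <= 0:
        raise ValueError("both axes must be positive")
    ratio = lateral_span_nm / height_nm
    if ratio < 1:
        ratio = 1.0 / ratio
    return (1.0 + 2.0 * ratio) / (1.0 + 2.0 / ratio)
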