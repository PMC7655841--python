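"""Precipitation-strengthening increment from a hardness contrast.

Dispersed nanoscopic obstacles that pin dislocations raise both hardness
and flow stress.  The flow-stress increment is recovered from the measured
hardness contrast through the linear constraint relation

    H = H0 + C * delta_sigma_Y

where H and H0 are the hardness of the obstacle-containing and pristine
crystal and C is the material-specific constraint coefficient relating
hardness to uniaxial flow stress (Tabor-style; default 3).  Adding the
increment to the pristine yield strength gives the predicted intrinsic
strength of the defect-containing crystal; when the prediction exceeds the
measured strength, yielding by dislocation motion is pre-empted by
fracture.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["HardnessPair", "strengthening_increment", "predicted_strength", "StrengthPrediction"]


@dataclass(frozen=True)
class HardnessPair:
    """Hardness of the defect-containing (H) and pristine (H0) crystal, GPa."""

    hardness_gpa: float
    reference_hardness_gpa: float
    constraint_coefficient: float = 3.0

    def __post_init__(self) -> None:
        if self.reference_hardness_gpa <= 0:
            raise ValueError("reference hardness must be positive")
        if self.constraint_coefficient <= 0:
            raise ValueError("constraint coefficient must be positive")


@dataclass(frozen=True)
class StrengthPrediction:
    """Predicted intrinsic strength and comparison against a measurement."""

    predicted_gpa: float
    measured_gpa: float | None
    fracture_before_yield: bool | None


def strengthening_increment(pair: HardnessPair) -> tuple[float, bool]:
    """Flow-stress increment delta_sigma_Y = (H - H0) / C, in GPa.

    Returns ``(increment, softening)``; ``softening`` flags a negative
    increment (H below H0), which is permitted but physically suspicious.
    """
    increment = (pair.hardness_gpa - pair.reference_hardness_gpa) / pair.constraint_coefficient
    return increment, increment < 0


def predicted_strength(
    base_strength_gpa: float,
    increment_gpa: float,
    measured_strength_gpa: float | None = None,
) -> StrengthPrediction:
    """Intrinsic strength prediction: base yield strength plus increment.

    If a measured strength is supplied, the ``fracture_before_yield`` flag
    fires when the prediction exceeds it: the crystal breaks before its
    dislocations could move.
    """
    predicted = base_strength_gpa + increment_gpa
    flag = None if measured_strength_gpa is None else predicted > measured_strength_gpa
    return StrengthPrediction(predicted, measured_strength_gpa, flag)
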