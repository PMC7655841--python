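"""Micro-pillar compression data reduction.

Raw uniaxial micro-pillar compression records (force in mN, depth in nm)
are converted to normalized engineering stress and strain with the
substrate-compliance (Sneddon-type) correction for a slightly tapered
pillar on an elastic half-space:

    eps_n   = delta / h
    sigma_n = (4 / (pi D1 D2) + (1 - nu^2) / (D2 h)) * F

where D1 and D2 are the top and bottom pillar diameters, h the height and
nu the Poisson ratio of the material (0.3 for calcite).  Scalar properties
are then extracted from the curve:

* Young's modulus E from a least-squares line over a stress window of the
  loading portion (default the 50-95 % stress levels),
* yield (onset of nonlinearity): the last point consistent with the
  elastic line, with sigma_Y = 4 F_Y / (pi D1^2),
* maximum strength sigma_max = 4 F_max / (pi D1^2) and failure strain
  eps_f at the abrupt terminal load drop,
* for curves with a displacement burst at yield: burst size delta_eps and
  the mean stress of the post-burst steady-flow plateau sigma_f.

Cohort statistics (per-group mean +/- sd and two-sample t tests) compare
material classes, e.g. biogenic against geological calcite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "PillarGeometry",
    "StressStrainCurve",
    "ModulusFit",
    "YieldResult",
    "MaxStrengthResult",
    "BurstResult",
    "MechanicalSummary",
    "normalize_curve",
    "fit_modulus",
    "detect_yield",
    "compute_max_strength",
    "detect_strain_burst",
    "reduce_curve",
    "summarize_cohort",
    "load_record",
    "load_geometry",
]

# unit conversions: instrument-native mN / nm / um -> SI
_MN = 1e-3  # mN -> N
_NM = 1e-9  # nm -> m
_UM = 1e-6  # um -> m
_GPA = 1e-9  # Pa -> GPa


@dataclass(frozen=True)
class PillarGeometry:
    """Tapered micro-pillar: top/bottom diameters, height (um), taper, nu.

    If a taper angle (degrees) is supplied it must be consistent with
    atan((D2 - D1) / (2 h)) within ``taper_tolerance_deg``.
    """

    top_diameter_um: float
    bottom_diameter_um: float
    height_um: float
    taper_deg: float | None = None
    poisson_ratio: float = 0.3
    taper_tolerance_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.top_diameter_um <= 0 or self.height_um <= 0:
            raise ValueError("pillar dimensions must be positive")
        if self.bottom_diameter_um < self.top_diameter_um:
            raise ValueError("bottom diameter must be >= top diameter")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.taper_deg is not None:
            implied = self.implied_taper_deg
            if abs(self.taper_deg - implied) > self.taper_tolerance_deg:
                raise ValueError(
                    f"stated taper {self.taper_deg:.3f} deg inconsistent with "
                    f"geometry-implied {implied:.3f} deg"
                )

    @property
    def implied_taper_deg(self) -> float:
        return math.degrees(
            math.atan((self.bottom_diameter_um - self.top_diameter_um) / (2.0 * self.height_um))
        )

    @property
    def stress_coefficient_gpa_per_mn(self) -> float:
        """sigma_n / F in GPa per mN for the taper-corrected formula."""
        d1 = self.top_diameter_um * _UM
        d2 = self.bottom_diameter_um * _UM
        h = self.height_um * _UM
        nu = self.poisson_ratio
        coeff = 4.0 / (math.pi * d1 * d2) + (1.0 - nu**2) / (d2 * h)  # 1/m^2
        return coeff * _MN * _GPA

    @property
    def yield_stress_coefficient_gpa_per_mn(self) -> float:
        """sigma / F in GPa per mN for the top-section formula 4F/(pi D1^2)."""
        d1 = self.top_diameter_um * _UM
        return 4.0 / (math.pi * d1**2) * _MN * _GPA


@dataclass
class StressStrainCurve:
    """Normalized engineering stress/strain with the raw record retained.

    The raw force is kept because the yield and maximum strengths use the
    top-section formula 4F/(pi D1^2), not the normalization coefficient.
    """

    strain: np.ndarray
    stress_gpa: np.ndarray
    force_mn: np.ndarray
    depth_nm: np.ndarray
    geometry: PillarGeometry
    segment: np.ndarray | None = None
    _loading: slice | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.strain.size

    def loading_slice(self) -> slice:
        """Indices of the loading portion.

        Uses the ``segment`` labels when present; otherwise the longest
        contiguous run of non-decreasing depth (raw exports often lack
        labels).
        """
        if self._loading is not None:
            return self._loading
        if self.segment is not None:
            idx = np.flatnonzero(self.segment == "loading")
            if idx.size:
                self._loading = slice(int(idx[0]), int(idx[-1]) + 1)
                return self._loading
        d = self.depth_nm
        rising = np.diff(d) >= -1e-12
        best_start, best_len, start = 0, 0, 0
        for i, ok in enumerate(np.append(rising, False)):
            if not ok:
                run = i - start + 1
                if run > best_len:
                    best_start, best_len = start, run
                start = i + 1
        self._loading = slice(best_start, best_start + best_len)
        return self._loading


def normalize_curve(record: pd.DataFrame, geometry: PillarGeometry) -> StressStrainCurve:
    """Convert a force-depth record to normalized engineering stress/strain.

    ``record`` needs columns ``force_mN`` and ``depth_nm`` (optionally
    ``segment``).  Strain is exactly zero where depth is zero and stress
    exactly zero where force is zero.
    """
    force = np.asarray(record["force_mN"], dtype=float)
    depth = np.asarray(record["depth_nm"], dtype=float)
    if force.shape != depth.shape:
        raise ValueError("force and depth series must have equal length")
    if np.any(force < 0):
        raise ValueError("forces must be non-negative")
    strain = depth * _NM / (geometry.height_um * _UM)
    stress = geometry.stress_coefficient_gpa_per_mn * force
    segment = (
        np.asarray(record["segment"], dtype=object) if "segment" in record else None
    )
    return StressStrainCurve(strain, stress, force, depth, geometry, segment)


@dataclass(frozen=True)
class ModulusFit:
    modulus_gpa: float
    r_squared: float
    n_points: int
    window: tuple[float, float]


def fit_modulus(
    curve: StressStrainCurve,
    window: tuple[float, float] = (0.50, 0.95),
) -> ModulusFit:
    """Young's modulus from a least-squares line on the windowed loading curve.

    The window selects points whose stress lies between the given
    fractions (default 50-95 %) of the *elastic portion* of the loading
    curve, which skips the seating nonlinearity at the foot and the
    yield knee at the top.  The end of the elastic portion is located
    with a provisional low-stress fit (25-50 % of peak), so hardening
    curves whose stress keeps rising past yield do not contaminate the
    regression.
    """
    lo, hi = window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("window must satisfy 0 <= lo < hi <= 1")
    sl = curve.loading_slice()
    strain = curve.strain[sl]
    stress = curve.stress_gpa[sl]
    # restrict to the rising portion up to peak stress
    peak = int(np.argmax(stress))
    strain, stress = strain[: peak + 1], stress[: peak + 1]
    smax = stress.max() if stress.size else 0.0

    # provisional elastic slope from the surely-elastic low-stress range;
    # deviation is judged on median-smoothed stress with 3-point
    # persistence so single noise dips cannot truncate the elastic range
    elastic_end = smax
    pmask = (stress >= 0.25 * smax) & (stress <= 0.50 * smax)
    if pmask.sum() >= 3:
        p_slope, p_icpt = np.polyfit(strain[pmask], stress[pmask], 1)
        line = p_slope * strain + p_icpt
        smoothed = ndimage.median_filter(stress, size=5, mode="nearest")
        with np.errstate(divide="ignore", invalid="ignore"):
            softening = np.where(line > 0.5 * smax, (line - smoothed) / line, 0.0)
        exceed = softening > 0.02
        persistent = exceed.copy()
        persistent[:-2] &= exceed[1:-1] & exceed[2:]
        dev = np.flatnonzero(persistent)
        if dev.size:
            elastic_end = float(stress[max(int(dev[0]) - 1, 0)])

    mask = (stress >= lo * elastic_end) & (stress <= hi * elastic_end)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points in the modulus window")
    slope, intercept = np.polyfit(strain[mask], stress[mask], 1)
    resid = stress[mask] - (slope * strain[mask] + intercept)
    ss_tot = float(np.sum((stress[mask] - stress[mask].mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return ModulusFit(float(slope), r2, int(mask.sum()), window)


@dataclass(frozen=True)
class YieldResult:
    detected: bool
    yield_force_mn: float | None = None
    yield_strength_gpa: float | None = None
    elastic_limit: float | None = None
    index: int | None = None


def detect_yield(
    curve: StressStrainCurve,
    modulus_gpa: float,
    offset_tolerance: float = 0.02,
    smooth_points: int = 5,
) -> YieldResult:
    """Onset of the nonlinear portion of the loading curve.

    The stress series is smoothed with a running median, and the yield
    point is the last loading point still consistent with the elastic
    line through the origin (relative softening below
    ``offset_tolerance``), requiring the deviation to persist for three
    consecutive points.  On gradually hardening curves the estimate is
    refined by intersecting the elastic line with a local fit of the
    post-yield branch.  sigma_Y = 4 F_Y / (pi D1^2) uses the top section
    only.  A purely elastic curve returns ``detected=False``.
    """
    sl = curve.loading_slice()
    strain = curve.strain[sl]
    stress = curve.stress_gpa[sl]
    force = curve.force_mn[sl]
    if strain.size < 5:
        return YieldResult(False)
    # keep the full loading segment: on burst-type curves the stress
    # maximum coincides with the yield point itself
    strain_l, stress_l = strain, stress

    smoothed = ndimage.median_filter(stress_l, size=smooth_points, mode="nearest")
    elastic = modulus_gpa * strain_l
    # softening deviation relative to the elastic line, with the
    # denominator floored at half the peak stress so transducer noise at
    # the foot of the curve cannot trigger a spurious detection
    denom = np.maximum(elastic, 0.5 * stress_l.max())
    deviation = (elastic - smoothed) / denom

    exceed = deviation > offset_tolerance
    persistent = exceed.copy()
    persistent[:-2] &= exceed[1:-1] & exceed[2:]
    persistent[-2:] = exceed[-2:]
    candidates = np.flatnonzero(persistent & (strain_l > 0))
    if candidates.size == 0:
        return YieldResult(False)
    first_dev = int(candidates[0])
    onset = max(first_dev - 1, 0)

    # refinement for smooth knees: fit the clearly-plastic branch and
    # intersect with the elastic line; accept only a local correction
    clear = np.flatnonzero(deviation > 2.0 * offset_tolerance)
    if clear.size >= 3:
        seg = clear[:20]
        b, a = np.polyfit(strain_l[seg], stress_l[seg], 1)
        if abs(modulus_gpa - b) > 1e-9:
            knee = a / (modulus_gpa - b)
            if knee > 0 and abs(knee - strain_l[onset]) <= 0.05 * strain_l[onset]:
                onset = int(np.argmin(np.abs(strain_l - knee)))

    idx_global = sl.start + onset
    f_y = float(force[onset])
    sigma_y = f_y * curve.geometry.yield_stress_coefficient_gpa_per_mn
    return YieldResult(True, f_y, sigma_y, float(strain_l[onset]), idx_global)


@dataclass(frozen=True)
class MaxStrengthResult:
    max_force_mn: float
    max_strength_gpa: float
    failure_strain: float | None
    failure_detected: bool
    strain_at_peak: float


def compute_max_strength(
    curve: StressStrainCurve,
    drop_fraction: float = 0.5,
    terminal_fraction: float = 0.3,
) -> MaxStrengthResult:
    """Maximum strength 4 F_max / (pi D1^2) and failure strain.

    Failure is an abrupt *terminal* load drop: a relative force drop
    exceeding ``drop_fraction`` within one step, from a level above half
    of the peak force, after which the load never recovers past
    ``terminal_fraction`` of the peak (a displacement burst followed by
    reloading to a flow plateau is yield, not fracture).
    ``failure_strain`` is the strain just before the drop; absent a drop
    it is None and flagged.
    """
    sl = curve.loading_slice()
    strain = curve.strain[sl]
    stress = curve.stress_gpa[sl]
    force = curve.force_mn[sl]
    f_max = float(force.max())
    sigma_max = f_max * curve.geometry.yield_stress_coefficient_gpa_per_mn

    failure_strain = None
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_drop = np.where(force[:-1] > 0, (force[:-1] - force[1:]) / force[:-1], 0.0)
    drops = np.flatnonzero((rel_drop > drop_fraction) & (force[:-1] > 0.5 * f_max))
    for i in drops:
        if np.max(force[i + 1 :], initial=0.0) < terminal_fraction * f_max:
            failure_strain = float(strain[int(i)])
            break
    return MaxStrengthResult(
        f_max,
        sigma_max,
        failure_strain,
        failure_strain is not None,
        float(strain[int(np.argmax(stress))]),
    )


@dataclass(frozen=True)
class BurstResult:
    detected: bool
    burst_strain: float | None = None
    burst_index: int | None = None
    flow_strength_gpa: float | None = None
    plateau_slice: tuple[int, int] | None = None


def detect_strain_burst(
    curve: StressStrainCurve,
    modulus_gpa: float | None = None,
    jump_factor: float = 5.0,
    slope_bound_fraction: float = 0.1,
) -> BurstResult:
    """Displacement burst at yield and the post-burst flow plateau.

    A burst step is a per-step strain increment exceeding ``jump_factor``
    times the median loading increment.  The flow strength sigma_f is the
    mean stress of the longest contiguous post-burst region whose local
    slope magnitude stays below ``slope_bound_fraction * E``.  Curves
    without a burst (e.g. hardening biogenic-type curves) return
    ``detected=False``.
    """
    sl = curve.loading_slice()
    strain = curve.strain[sl]
    stress = curve.stress_gpa[sl]
    if strain.size < 10:
        return BurstResult(False)
    d_eps = np.diff(strain)
    med = float(np.median(d_eps[d_eps > 0])) if np.any(d_eps > 0) else 0.0
    if med <= 0:
        return BurstResult(False)
    bursts = np.flatnonzero(d_eps > jump_factor * med)
    if bursts.size == 0:
        return BurstResult(False)
    i = int(bursts[0])
    burst_strain = float(d_eps[i])

    if modulus_gpa is None:
        modulus_gpa = fit_modulus(curve).modulus_gpa
    bound = slope_bound_fraction * modulus_gpa

    # local slope on the post-burst portion
    post = slice(i + 1, strain.size)
    s, z = strain[post], stress[post]
    if s.size < 3:
        return BurstResult(True, burst_strain, sl.start + i)
    # local slope via a Savitzky-Golay derivative: a point-wise gradient
    # over one strain step would amplify stress noise far past the bound
    if s.size >= 11:
        from scipy.signal import savgol_filter

        window = min(41, s.size if s.size % 2 else s.size - 1)
        step = float(np.median(np.diff(s)))
        slope = savgol_filter(z, window, polyorder=1, deriv=1, delta=step)
    else:
        slope = np.gradient(z, s)
    flat = np.abs(slope) < bound
    # longest contiguous flat run
    best = (0, 0)
    start = None
    for j, ok in enumerate(np.append(flat, False)):
        if ok and start is None:
            start = j
        elif not ok and start is not None:
            if j - start > best[1] - best[0]:
                best = (start, j)
            start = None
    if best[1] - best[0] < 3:
        return BurstResult(True, burst_strain, sl.start + i)
    plateau = z[best[0] : best[1]]
    return BurstResult(
        True,
        burst_strain,
        sl.start + i,
        float(plateau.mean()),
        (sl.start + i + 1 + best[0], sl.start + i + 1 + best[1]),
    )


@dataclass
class MechanicalSummary:
    """Scalar mechanical properties of one pillar."""

    modulus_gpa: float
    yield_strength_gpa: float | None
    max_strength_gpa: float
    elastic_limit: float | None
    failure_strain: float | None
    flow_strength_gpa: float | None = None
    burst_strain: float | None = None
    yield_force_mn: float | None = None
    max_force_mn: float | None = None
    modulus_r_squared: float | None = None
    label: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def reduce_curve(
    record: pd.DataFrame,
    geometry: PillarGeometry,
    label: str | None = None,
    offset_tolerance: float = 0.02,
    drop_fraction: float = 0.5,
    modulus_window: tuple[float, float] = (0.50, 0.95),
) -> MechanicalSummary:
    """Full reduction of one pillar record to a MechanicalSummary."""
    curve = normalize_curve(record, geometry)
    mod = fit_modulus(curve, modulus_window)
    yld = detect_yield(curve, mod.modulus_gpa, offset_tolerance)
    mx = compute_max_strength(curve, drop_fraction)
    burst = detect_strain_burst(curve, mod.modulus_gpa)
    return MechanicalSummary(
        modulus_gpa=mod.modulus_gpa,
        yield_strength_gpa=yld.yield_strength_gpa,
        max_strength_gpa=mx.max_strength_gpa,
        elastic_limit=yld.elastic_limit,
        failure_strain=mx.failure_strain,
        flow_strength_gpa=burst.flow_strength_gpa,
        burst_strain=burst.burst_strain,
        yield_force_mn=yld.yield_force_mn,
        max_force_mn=mx.max_force_mn,
        modulus_r_squared=mod.r_squared,
        label=label,
    )


_COHORT_PROPERTIES = [
    "modulus_gpa",
    "yield_strength_gpa",
    "max_strength_gpa",
    "elastic_limit",
    "failure_strain",
    "flow_strength_gpa",
]


def summarize_cohort(
    summaries: list[MechanicalSummary],
    equal_var: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean +/- sd and pairwise two-sample t tests.

    Groups are the ``label`` fields of the summaries.  Returns
    ``(group_stats, pairwise_tests)``; groups with a single observation
    get NaN dispersion.  Properties absent from a group (e.g. flow
    strength for hardening curves) are dropped pairwise.
    """
    df = pd.DataFrame([s.to_dict() for s in summaries])
    if df["label"].isna().any():
        raise ValueError("every summary needs a group label")
    stats_rows = []
    for label, grp in df.groupby("label"):
        for prop in _COHORT_PROPERTIES:
            vals = grp[prop].dropna().astype(float)
            if vals.empty:
                continue
            stats_rows.append(
                {
                    "group": label,
                    "property": prop,
                    "n": len(vals),
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                }
            )
    group_stats = pd.DataFrame(stats_rows)

    labels = sorted(df["label"].unique())
    test_rows = []
    for a_idx in range(len(labels)):
        for b_idx in range(a_idx + 1, len(labels)):
            ga = df[df["label"] == labels[a_idx]]
            gb = df[df["label"] == labels[b_idx]]
            for prop in _COHORT_PROPERTIES:
                va = ga[prop].dropna().astype(float)
                vb = gb[prop].dropna().astype(float)
                if len(va) < 2 or len(vb) < 2:
                    continue
                t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
                test_rows.append(
                    {
                        "group_a": labels[a_idx],
                        "group_b": labels[b_idx],
                        "property": prop,
                        "t": float(t),
                        "p_value": float(p),
                        "significant_0.05": bool(p < 0.05),
                    }
                )
    return group_stats, pd.DataFrame(test_rows)


def load_record(path: str | Path) -> pd.DataFrame:
    """Read a compression record CSV (time_s, force_mN, depth_nm[, segment])."""
    df = pd.read_csv(path)
    missing = {"force_mN", "depth_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"record at {path} lacks columns {sorted(missing)}")
    if "time_s" in df and not np.all(np.diff(df["time_s"]) >= 0):
        raise ValueError("time must be non-decreasing")
    return df


def load_geometry(path: str | Path) -> PillarGeometry:
    """Read pillar geometry from a flat key = value text file.

    Keys: D1_um, D2_um, h_um, optional taper_deg, optional poisson.
    """
    values: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, raw = line.partition("=")
        values[key.strip()] = float(raw)
    return PillarGeometry(
        top_diameter_um=values["D1_um"],
        bottom_diameter_um=values["D2_um"],
        height_um=values["h_um"],
        taper_deg=values.get("taper_deg"),
        poisson_ratio=values.get("poisson", 0.3),
    )
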