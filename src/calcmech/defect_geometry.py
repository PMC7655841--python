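"""Geometry statistics of intracrystalline defect populations.

Digitized defect contours (2D point sets in nm, from TEM sections) are
fitted with ellipses; populations are summarized by semi-axis and
orientation statistics and a mean radial contour; spatial structure is
quantified by nearest-neighbour spacing (optionally partitioned by local
density class) and by the inclination-versus-distance profile relative to
the intercrystalline boundary.

Conventions: section coordinates in nm with y along the prism longitudinal
(c-axis) direction; ellipse orientation is the angle of the major axis
from the transverse (x) axis, reported in (-90, 90] degrees, so 0 means a
defect lying flat in the transverse plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import EllipseModel

__all__ = [
    "DefectContour",
    "EllipseFit",
    "DefectField",
    "SpacingStatistics",
    "fit_ellipse",
    "population_summary",
    "nearest_neighbor_spacing",
    "classify_density",
    "orientation_profile",
]


@dataclass(frozen=True)
class DefectContour:
    """Ordered contour points (N, 2) in nm with the section orientation."""

    points: np.ndarray
    section: str = "longitudinal"  # "longitudinal" | "transverse"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
            raise ValueError("contour needs at least 5 points of shape (N, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour points must be finite")
        object.__setattr__(self, "points", pts)
        if self.section not in ("longitudinal", "transverse"):
            raise ValueError("section must be 'longitudinal' or 'transverse'")


@dataclass(frozen=True)
class EllipseFit:
    """Fitted ellipse: centre (nm), semi-axes (nm), major-axis angle (deg)."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation_deg: float

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError("need semi_major >= semi_minor > 0")


class EllipseFitError(RuntimeError):
    """Raised when contour points cannot support an ellipse fit."""


def _wrap_angle_deg(angle: float) -> float:
    """Wrap to (-90, 90]."""
    a = (angle + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


def fit_ellipse(contour: DefectContour | np.ndarray) -> EllipseFit:
    """Least-squares conic fit constrained to an ellipse.

    Uses the numerically stable direct least-squares estimator; degenerate
    (e.g. collinear) point sets raise :class:`EllipseFitError`.
    """
    pts = contour.points if isinstance(contour, DefectContour) else np.asarray(contour, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise EllipseFitError("need at least 5 points of shape (N, 2)")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise EllipseFitError("degenerate contour: ellipse fit failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.all(np.isfinite([xc, yc, a, b, theta])) and a > 0 and b > 0):
        raise EllipseFitError("degenerate contour: non-finite or flat ellipse")
    # axis_lengths is major-first and theta refers to the major axis
    return EllipseFit((float(xc), float(yc)), float(a), float(b), _wrap_angle_deg(np.degrees(theta)))


@dataclass(frozen=True)
class PopulationSummary:
    n: int
    semi_major_mean: float
    semi_major_sd: float | None
    semi_minor_mean: float
    semi_minor_sd: float | None
    orientation_mean_deg: float
    orientation_sd_deg: float | None
    mean_contour: np.ndarray | None  # (n_angles, 2), centred at the origin


def population_summary(
    fits: list[EllipseFit],
    contours: list[DefectContour] | None = None,
    n_angles: int = 64,
) -> PopulationSummary:
    """Size/orientation statistics and the mean radial contour.

    The mean contour re-centres every contour on its fitted centre,
    samples the radius on a common angular grid by periodic interpolation
    and averages across defects; it reproduces any single ellipse exactly
    when all members are identical.
    """
    if not fits:
        raise ValueError("need at least one fit")
    a = np.array([f.semi_major for f in fits])
    b = np.array([f.semi_minor for f in fits])
    th = np.array([f.orientation_deg for f in fits])
    sd = (lambda v: float(np.std(v, ddof=1))) if len(fits) > 1 else (lambda v: None)

    mean_contour = None
    if contours:
        grid = np.linspace(-np.pi, np.pi, n_angles, endpoint=False)
        radii = np.zeros((len(contours), n_angles))
        for i, (contour, fit) in enumerate(zip(contours, fits)):
            rel = contour.points - np.asarray(fit.center)
            ang = np.arctan2(rel[:, 1], rel[:, 0])
            rad = np.hypot(rel[:, 0], rel[:, 1])
            order = np.argsort(ang)
            ang, rad = ang[order], rad[order]
            # periodic interpolation on the angular grid
            ang_ext = np.concatenate([ang - 2 * np.pi, ang, ang + 2 * np.pi])
            rad_ext = np.tile(rad, 3)
            radii[i] = np.interp(grid, ang_ext, rad_ext)
        mean_r = radii.mean(axis=0)
        mean_contour = np.column_stack([mean_r * np.cos(grid), mean_r * np.sin(grid)])

    return PopulationSummary(
        n=len(fits),
        semi_major_mean=float(a.mean()),
        semi_major_sd=sd(a),
        semi_minor_mean=float(b.mean()),
        semi_minor_sd=sd(b),
        orientation_mean_deg=float(th.mean()),
        orientation_sd_deg=sd(th),
        mean_contour=mean_contour,
    )


@dataclass(frozen=True)
class DefectField:
    """Fitted defects with positions; optional boundary polyline.

    ``centers`` is (N, 2) in nm; ``boundary`` is an (M, 2) polyline
    tracing the intercrystalline organic interface, if available.
    ``zone`` optionally labels each defect (e.g. density zones from a
    generator or from :func:`classify_density`).
    """

    fits: list[EllipseFit]
    boundary: np.ndarray | None = None
    zone: np.ndarray | None = None

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.fits])

    def __len__(self) -> int:
        return len(self.fits)


@dataclass(frozen=True)
class SpacingStatistics:
    n: int
    mean: float
    median: float
    sd: float
    distances: np.ndarray


def _nn_stats(centers: np.ndarray, radii: np.ndarray | None) -> SpacingStatistics:
    tree = cKDTree(centers)
    dist, idx = tree.query(centers, k=2)
    nn = dist[:, 1]
    if radii is not None:
        nn = nn - radii - radii[idx[:, 1]]
    return SpacingStatistics(
        n=centers.shape[0],
        mean=float(nn.mean()),
        median=float(np.median(nn)),
        sd=float(nn.std(ddof=1)) if nn.size > 1 else float("nan"),
        distances=nn,
    )


def nearest_neighbor_spacing(
    field: DefectField,
    definition: str = "center",
    by_zone: bool = False,
) -> SpacingStatistics | dict[str, SpacingStatistics]:
    """Nearest-neighbour defect spacing L (nm).

    ``definition="center"`` (primary) measures centre-to-centre;
    ``"edge"`` subtracts the mean radius of both ellipses as an
    edge-to-edge approximation.  With ``by_zone=True`` the statistics are
    computed within each zone label separately (neighbours restricted to
    the same zone), which isolates per-zone lattice spacings.
    """
    centers = field.centers
    if centers.shape[0] < 2:
        raise ValueError("need at least 2 defects for spacing")
    radii = None
    if definition == "edge":
        radii = np.array([(f.semi_major + f.semi_minor) / 2.0 for f in field.fits])
    elif definition != "center":
        raise ValueError("definition must be 'center' or 'edge'")
    if not by_zone:
        return _nn_stats(centers, radii)
    if field.zone is None:
        raise ValueError("field has no zone labels")
    out: dict[str, SpacingStatistics] = {}
    for label in np.unique(field.zone):
        mask = field.zone == label
        if mask.sum() < 2:
            continue
        out[str(label)] = _nn_stats(centers[mask], None if radii is None else radii[mask])
    return out


def classify_density(
    field: DefectField,
    radius_nm: float = 50.0,
) -> np.ndarray:
    """Label defects "high"/"low" by local count within ``radius_nm``.

    The threshold is the field-median local count; ties go to "high".
    """
    centers = field.centers
    tree = cKDTree(centers)
    counts = np.array([len(tree.query_ball_point(c, radius_nm)) - 1 for c in centers])
    threshold = np.median(counts)
    return np.where(counts >= threshold, "high", "low")


def _distance_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Shortest distance from each point to a polyline."""
    from shapely import LineString, Point

    line = LineString(polyline)
    return np.array([line.distance(Point(p)) for p in points])


@dataclass(frozen=True)
class OrientationProfile:
    bin_centers_nm: np.ndarray
    mean_abs_theta_deg: np.ndarray
    counts: np.ndarray
    monotonic_decreasing: bool


def orientation_profile(
    field: DefectField,
    bin_width_nm: float = 50.0,
    max_distance_nm: float | None = None,
) -> OrientationProfile:
    """Binned mean |inclination| versus distance to the boundary.

    Requires the field's boundary polyline.  The monotonicity diagnostic
    reports whether the binned means are non-increasing with distance
    (defects flattening into the transverse plane away from the
    interface).
    """
    if field.boundary is None:
        raise ValueError("field has no boundary polyline")
    centers = field.centers
    theta = np.abs([f.orientation_deg for f in field.fits])
    dist = _distance_to_polyline(centers, np.asarray(field.boundary, float))
    if max_distance_nm is None:
        max_distance_nm = float(dist.max())
    edges = np.arange(0.0, max_distance_nm + bin_width_nm, bin_width_nm)
    idx = np.digitize(dist, edges) - 1
    centers_out, means, counts = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not mask.any():
            continue
        centers_out.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(float(theta[mask].mean()))
        counts.append(int(mask.sum()))
    means_arr = np.asarray(means)
    mono = bool(np.all(np.diff(means_arr) <= 1e-9)) if means_arr.size > 1 else True
    return OrientationProfile(np.asarray(centers_out), means_arr, np.asarray(counts), mono)
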