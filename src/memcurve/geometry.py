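"""Mid-surface geometry of flat and cylindrically curved membranes.

The membrane mid-surface is modelled either as a plane (zero curvature) or
as a circular cylinder whose axis is the laboratory Y axis, so all curvature
lives in the XZ plane.  The signed curvature ``c`` follows the convention
that ``c > 0`` means the *outer* monolayer is convex: the :class:`SurfaceModel`
stores explicitly which side of the surface the outer leaflet faces, and the
signed depth coordinate is positive toward the outer leaflet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SurfaceModel",
    "SectorSpec",
    "make_surface",
    "fit_surface",
    "signed_depth",
    "outer_normal",
    "sector_mask",
    "InvalidParameterError",
    "FitDegenerateError",
    "UndefinedNormalError",
    "InvalidSectorModeError",
]

#: sanity bound on |c| (nm^-1); tighter radii than 1 nm are not membranes
MAX_ABS_CURVATURE = 1.0


class InvalidParameterError(ValueError):
    """Raised when a geometric parameter is outside its physical range."""


class FitDegenerateError(ValueError):
    """Raised when the point cloud cannot determine the requested surface."""


class UndefinedNormalError(ValueError):
    """Raised when the outer normal is undefined (point on the cylinder axis)."""


class InvalidSectorModeError(ValueError):
    """Raised when a sector mode is incompatible with the surface kind."""


@dataclass(frozen=True)
class SurfaceModel:
    """Plane or Y-axis cylinder representing the membrane mid-surface.

    Parameters
    ----------
    kind
        ``"plane"`` or ``"cylinder"``.
    z0
        Plane reference height (nm); used only for ``kind="plane"``.
    outer_sign
        For a plane: +1 if the outer leaflet faces +Z, -1 otherwise.
        For a cylinder: +1 if the outer leaflet faces radially outward
        (outer monolayer convex, ``c > 0``), -1 if it faces the axis.
    center
        Cylinder axis position ``(cx, cz)`` in the XZ plane (nm).
    radius
        Cylinder radius (nm), > 0.
    ref_dir
        Unit 2-vector in XZ from the axis toward the bicelle symmetry
        plane; arc angles in :func:`sector_mask` are measured from it.
    x0
        X coordinate of the symmetry plane for slab sectors on a plane.
    """

    kind: Literal["plane", "cylinder"]
    z0: float = 0.0
    outer_sign: int = 1
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 0.0
    ref_dir: tuple[float, float] = (0.0, 1.0)
    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("plane", "cylinder"):
            raise InvalidParameterError(f"unknown surface kind {self.kind!r}")
        if self.outer_sign not in (1, -1):
            raise InvalidParameterError("outer_sign must be +1 or -1")
        if self.kind == "cylinder" and not self.radius > 0:
            raise InvalidParameterError("cylinder radius must be positive")

    @property
    def curvature(self) -> float:
        """Signed curvature c (nm^-1); 0 for a plane, outer_sign/R for a cylinder."""
        if self.kind == "plane":
            return 0.0
        return self.outer_sign / self.radius


@dataclass(frozen=True)
class SectorSpec:
    """Analysis sector excluding the bicelle caps.

    ``arc`` mode selects points whose arc angle from the symmetry plane is
    within ``half_angle_deg`` (cylinders only); ``slab`` mode selects points
    with ``|x - x0| <= half_width_nm`` (flat membranes).
    """

    mode: Literal["arc", "slab"]
    half_angle_deg: float = 30.0
    half_width_nm: float = 3.0

    def __post_init__(self) -> None:
        if self.mode == "arc" and not (0.0 < self.half_angle_deg <= 90.0):
            raise InvalidParameterError("arc half-angle must be in (0, 90] degrees")
        if self.mode == "slab" and not self.half_width_nm > 0:
            raise InvalidParameterError("slab half-width must be positive")


def make_surface(c: float, anchor_point=(0.0, 0.0, 0.0)) -> SurfaceModel:
    """Build the mid-surface of signed curvature ``c`` through ``anchor_point``.

    ``c = 0`` yields the plane ``z = anchor_z`` with the outer leaflet facing
    +Z.  ``c != 0`` yields a cylinder of radius ``1/|c|`` with axis along Y,
    positioned so that the outer normal at the anchor point is +Z: for
    ``c > 0`` the axis lies below the anchor (outer leaflet convex), for
    ``c < 0`` above it (outer leaflet concave).
    """
    if not np.isfinite(c) or abs(c) >= MAX_ABS_CURVATURE:
        raise InvalidParameterError(
            f"|c| must be < {MAX_ABS_CURVATURE} nm^-1, got {c}"
        )
    ax, _ay, az = (float(v) for v in np.asarray(anchor_point, dtype=float))
    if c == 0.0:
        return SurfaceModel(kind="plane", z0=az, outer_sign=1, x0=ax)
    R = 1.0 / abs(c)
    s = 1 if c > 0 else -1
    # axis placed so the outer normal at the anchor is +Z
    center = (ax, az - s * R)
    ref = (0.0, float(s))  # from axis toward the anchor
    return SurfaceModel(
        kind="cylinder", outer_sign=s, center=center, radius=R, ref_dir=ref, x0=ax
    )


def _kasa_circle(x: np.ndarray, z: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kåsa) circle fit; returns (cx, cz, R)."""
    A = np.column_stack([2 * x, 2 * z, np.ones_like(x)])
    b = x**2 + z**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cz, k = sol
    R = float(np.sqrt(k + cx**2 + cz**2))
    return float(cx), float(cz), R


def fit_surface(
    points,
    kind_hint: Literal["auto", "plane", "cylinder"] = "auto",
    outer_hint=(0.0, 0.0, 1.0),
) -> SurfaceModel:
    """Least-squares fit of a plane or Y-axis cylinder mid-surface.

    Cylinders are fitted as circles in the XZ projection: an algebraic Kåsa
    fit provides the initializer, refined by geometric least squares on the
    radial residuals.  ``outer_hint`` declares which way the outer leaflet
    faces (default +Z); the fitted model's sign convention follows it, so
    the reported signed curvature matches the convention that positive
    curvature means a convex outer monolayer.

    ``kind_hint="auto"`` falls back to a plane when the fitted radius is so
    large that the surface is flat to within 1e-6 nm over the data extent.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidParameterError("points must be an (N, 3) array")
    x, z = pts[:, 0], pts[:, 2]
    n = len(pts)
    hint = np.asarray(outer_hint, dtype=float)

    if kind_hint == "plane":
        if n < 3:
            raise FitDegenerateError("plane fit needs >= 3 points")
        s = 1 if hint[2] >= 0 else -1
        return SurfaceModel(kind="plane", z0=float(z.mean()), outer_sign=s,
                            x0=float(x.mean()))

    if n < 6:
        raise FitDegenerateError("cylinder fit needs >= 6 points")
    # collinearity check in XZ
    xz = np.column_stack([x, z])
    sv = np.linalg.svd(xz - xz.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        if kind_hint == "cylinder":
            raise FitDegenerateError("points are collinear in the XZ projection")
        s = 1 if hint[2] >= 0 else -1
        return SurfaceModel(kind="plane", z0=float(z.mean()), outer_sign=s,
                            x0=float(x.mean()))

    cx, cz, R = _kasa_circle(x, z)

    def residuals(p):
        return np.hypot(x - p[0], z - p[1]) - p[2]

    sol = least_squares(residuals, [cx, cz, R], xtol=1e-14, ftol=1e-14, gtol=1e-14)
    cx, cz, R = (float(v) for v in sol.x)

    if kind_hint == "auto":
        # flat to numerical precision over the data span -> plane
        span = float(np.ptp(x))
        sagitta = R - np.sqrt(max(R**2 - (span / 2) ** 2, 0.0)) if R > span / 2 else R
        if R > 1e6 or sagitta < 1e-9:
            s = 1 if hint[2] >= 0 else -1
            return SurfaceModel(kind="plane", z0=float(z.mean()), outer_sign=s,
                                x0=float(x.mean()))

    # orient: outer leaflet faces radially outward iff the hint points away
    # from the axis at the data centroid
    centroid = np.array([x.mean(), z.mean()])
    radial = centroid - np.array([cx, cz])
    rn = np.linalg.norm(radial)
    if rn == 0:
        raise FitDegenerateError("data centroid coincides with the fitted axis")
    radial /= rn
    s = 1 if float(radial[0] * hint[0] + radial[1] * hint[2]) >= 0 else -1
    return SurfaceModel(
        kind="cylinder",
        outer_sign=s,
        center=(cx, cz),
        radius=R,
        ref_dir=(float(radial[0]), float(radial[1])),
        x0=float(x.mean()),
    )


def signed_depth(surface: SurfaceModel, point) -> float | np.ndarray:
    """Signed distance from the mid-surface: positive toward the outer leaflet.

    Accepts a single point or an (N, 3) array; for a cylinder this is
    ``s * (||p_XZ - center|| - R)``.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if surface.kind == "plane":
        d = surface.outer_sign * (p[:, 2] - surface.z0)
    else:
        cx, cz = surface.center
        d = surface.outer_sign * (
            np.hypot(p[:, 0] - cx, p[:, 2] - cz) - surface.radius
        )
    return float(d[0]) if single else d


def outer_normal(surface: SurfaceModel, point, leaflet: str = "outer") -> np.ndarray:
    """Unit outer normal at ``point`` (the gradient of the signed depth).

    For the outer leaflet the normal points away from the mid-surface on the
    outer side; the inner-leaflet normal is its negation.
    """
    if leaflet not in ("outer", "inner"):
        raise InvalidParameterError(f"unknown leaflet {leaflet!r}")
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if surface.kind == "plane":
        n = np.zeros_like(p)
        n[:, 2] = surface.outer_sign
    else:
        cx, cz = surface.center
        dx, dz = p[:, 0] - cx, p[:, 2] - cz
        r = np.hypot(dx, dz)
        if np.any(r < 1e-12):
            raise UndefinedNormalError("point lies on the cylinder axis")
        n = np.zeros_like(p)
        n[:, 0] = surface.outer_sign * dx / r
        n[:, 2] = surface.outer_sign * dz / r
    if leaflet == "inner":
        n = -n
    return n[0] if single else n


def arc_angle(surface: SurfaceModel, point) -> float | np.ndarray:
    """Arc angle (degrees) from the bicelle symmetry plane, cylinder only."""
    if surface.kind != "cylinder":
        raise InvalidSectorModeError("arc angle is defined on cylinders only")
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    cx, cz = surface.center
    rx, rz = surface.ref_dir
    dx, dz = p[:, 0] - cx, p[:, 2] - cz
    # angle between (dx, dz) and ref_dir
    dot = dx * rx + dz * rz
    cross = dx * rz - dz * rx
    ang = np.degrees(np.abs(np.arctan2(cross, dot)))
    return float(ang[0]) if single else ang


def sector_mask(surface: SurfaceModel, points, sector: SectorSpec | None) -> np.ndarray:
    """Boolean mask of points inside the analysis sector.

    ``None`` selects everything.  Arc sectors require a cylinder surface;
    slab sectors test ``|x - x0|`` and work on either kind.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if sector is None:
        return np.ones(len(pts), dtype=bool)
    if sector.mode == "arc":
        if surface.kind != "cylinder":
            raise InvalidSectorModeError("arc sector requires a cylinder surface")
        return np.asarray(arc_angle(surface, pts)) <= sector.half_angle_deg
    return np.abs(pts[:, 0] - surface.x0) <= sector.half_width_nm
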