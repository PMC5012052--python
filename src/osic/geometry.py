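"""Corridor geometry: projected angles, safety angles, widths, centered axes.

An optimal implant is the segment from an insertion point ``I`` on the
ventral bone surface to an exit point ``E``.  Its 3D direction is reported
as two projected angles (ProjA) measured in the anatomical planes of the
vertebra it belongs to.  The angular safety margin toward each of four
safety points ``S`` is the safety angle (SafA): the angle between the
implant axis and the tangent line, from ``I``, to a circle of implant
radius ``r`` centred on ``S``.  Corridor widths are estimated in the two
orthogonal safety planes from the perpendicular offsets of the safety
points.  Centered axes of the simplified corridor shapes (pyramid, prism,
hemi-ellipsoid) provide the optimal axis each implant is placed on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .frames import _as_point

__all__ = [
    "UndefinedDirectionError",
    "TangentUndefinedError",
    "DegenerateShapeError",
    "ZeroLengthImplantError",
    "CollinearSafetyPointWarning",
    "NonOrthogonalPlanesWarning",
    "ProjectedAngles",
    "ImplantAxis",
    "SafetyMargins",
    "SafetyAngles",
    "CorridorShape",
    "SiteDescriptor",
    "load_site_catalog",
    "projected_angles",
    "direction_from_angles",
    "safety_angle",
    "safety_angles",
    "corridor_width",
    "centered_axis",
    "simulate_optimal_implant",
]


class UndefinedDirectionError(ValueError):
    """Implant vector has zero length; its direction is undefined."""


class TangentUndefinedError(ValueError):
    """No tangent from the insertion point exists (|S - I| <= r)."""


class DegenerateShapeError(ValueError):
    """Corridor shape has no well-defined centered axis."""


class ZeroLengthImplantError(ValueError):
    """Boundary sets project to the same axis position."""


class CollinearSafetyPointWarning(UserWarning):
    """Safety point lies on the implant axis; SafA reduces to -arcsin(r/|SI|)."""


class NonOrthogonalPlanesWarning(UserWarning):
    """The two safety-point planes deviate from orthogonality by more than 5 deg."""


# --------------------------------------------------------------------------
# site catalog

@dataclass(frozen=True)
class SiteDescriptor:
    site_id: str
    corridor: str
    vertebra: str
    laterality: str
    frame: str                      # which vertebral frame ProjA projects in
    shape: str                      # pyramid | prism | hemi_ellipsoid
    projection_pair: tuple          # reported angle names, 1 for sagittal sites
    sagittal_site: bool
    canal_directed: bool            # sagittal implant aimed at the vertebral canal


def load_site_catalog() -> dict[str, SiteDescriptor]:
    """Load the packaged 13-site implant catalog, keyed by site id."""
    raw = json.loads(
        resources.files("osic.data").joinpath("site_catalog.json").read_text()
    )
    catalog = {}
    for entry in raw["sites"]:
        d = SiteDescriptor(
            site_id=entry["site_id"],
            corridor=entry["corridor"],
            vertebra=entry["vertebra"],
            laterality=entry["laterality"],
            frame=entry["frame"],
            shape=entry["shape"],
            projection_pair=tuple(entry["projection_pair"]),
            sagittal_site=entry["sagittal_site"],
            canal_directed=entry["canal_directed"],
        )
        catalog[d.site_id] = d
    if len(catalog) != 13:
        raise ValueError(f"site catalog must define 13 sites, got {len(catalog)}")
    return catalog


# --------------------------------------------------------------------------
# projected angles

@dataclass(frozen=True)
class ProjectedAngles:
    """The three projected angles (degrees) of an implant direction.

    ``sagittal`` is measured in the sagittal (X-Z) plane, ``dorsal`` in the
    dorsal (X-Y) plane and ``transverse`` in the transverse (Z-Y) plane,
    each as the two-argument arctangent of the off-axis over the reference
    component.  ``reported_pair`` holds the catalog-selected angle(s) that
    serve as the implant's coordinates (one angle for sagittal sites).
    ``indeterminate`` names angles whose projection has vanishing in-plane
    magnitude.
    """

    sagittal: float
    dorsal: float
    transverse: float
    reported_pair: tuple
    indeterminate: tuple = ()

    def as_dict(self) -> dict:
        return {"sagittal": self.sagittal, "dorsal": self.dorsal,
                "transverse": self.transverse}


_PLANE_COMPONENTS = {
    # angle name -> (numerator index, denominator/reference index) into (x, y, z)
    "sagittal": (2, 0),     # atan2(z, x): in-plane deviation from craniocaudal
    "dorsal": (1, 0),       # atan2(y, x)
    "transverse": (1, 2),   # atan2(y, z): zero reference is ventrodorsal
}


def projected_angles(v, site: SiteDescriptor | None = None) -> ProjectedAngles:
    """Projected angles (degrees) of an anatomical-frame vector ``v``.

    ``v`` has (craniocaudal, mediolateral, ventrodorsal) components.  Each
    projected angle is the signed angle, in one anatomical plane, between
    the projection of ``v`` and the plane's reference axis, computed as a
    two-argument arctangent so the full (-180, 180] range is available.

    Raises :class:`UndefinedDirectionError` for a zero vector.  Angles
    whose two in-plane components are both zero are flagged indeterminate
    (and reported as 0.0).
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-component vector, got shape {v.shape}")
    n = np.linalg.norm(v)
    if n == 0.0:
        raise UndefinedDirectionError("zero-length implant vector")
    vals, indeterminate = {}, []
    for name, (i_num, i_ref) in _PLANE_COMPONENTS.items():
        num, ref = v[i_num], v[i_ref]
        if num == 0.0 and ref == 0.0:
            indeterminate.append(name)
            vals[name] = 0.0
        else:
            vals[name] = float(np.degrees(np.arctan2(num, ref)))
    pair_names = site.projection_pair if site is not None else ("sagittal", "dorsal")
    pair = tuple(vals[p] for p in pair_names)
    return ProjectedAngles(sagittal=vals["sagittal"], dorsal=vals["dorsal"],
                           transverse=vals["transverse"], reported_pair=pair,
                           indeterminate=tuple(indeterminate))


def direction_from_angles(sagittal: float, dorsal: float) -> np.ndarray:
    """Unit anatomical-frame direction with prescribed sagittal/dorsal ProjA.

    Valid for |angle| < 90 deg (positive craniocaudal component).  Inverse
    of :func:`projected_angles` restricted to the reported pair.
    """
    if not (abs(sagittal) < 90.0 and abs(dorsal) < 90.0):
        raise ValueError("prescribed projected angles must satisfy |angle| < 90 deg")
    d = np.array([1.0, np.tan(np.radians(dorsal)), np.tan(np.radians(sagittal))])
    return d / np.linalg.norm(d)


# --------------------------------------------------------------------------
# implant axis, safety margins

@dataclass(frozen=True)
class ImplantAxis:
    """Optimal implant segment from insertion ``I`` to exit ``E`` (mm)."""

    insertion_I: np.ndarray
    exit_E: np.ndarray
    site_id: str = ""
    frame_ref: str = "C2"

    def __post_init__(self):
        object.__setattr__(self, "insertion_I", _as_point(self.insertion_I))
        object.__setattr__(self, "exit_E", _as_point(self.exit_E))
        if np.linalg.norm(self.exit_E - self.insertion_I) == 0.0:
            raise ZeroLengthImplantError("insertion and exit points coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.exit_E - self.insertion_I))

    @property
    def direction(self) -> np.ndarray:
        d = self.exit_E - self.insertion_I
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class SafetyMargins:
    """Four safety points in two orthogonal planes through the implant axis."""

    S1: np.ndarray
    S2: np.ndarray
    S3: np.ndarray
    S4: np.ndarray
    implant_radius_r: float = 0.75  # mm; half the 1.5 mm implant diameter

    def __post_init__(self):
        for name in ("S1", "S2", "S3", "S4"):
            object.__setattr__(self, name, _as_point(getattr(self, name)))
        if self.implant_radius_r < 0:
            raise ValueError("implant radius must be non-negative")

    @property
    def points(self) -> list[np.ndarray]:
        return [self.S1, self.S2, self.S3, self.S4]


@dataclass(frozen=True)
class SafetyAngles:
    """Four SafA (deg), the two in-plane corridor widths (mm) and length (mm)."""

    saf_a1: float
    saf_a2: float
    saf_a3: float
    saf_a4: float
    width_plane1: float
    width_plane2: float
    implant_length: float
    negative_flags: tuple = ()

    @property
    def values(self) -> tuple:
        return (self.saf_a1, self.saf_a2, self.saf_a3, self.saf_a4)


def safety_angle(I, E, S, r: float) -> float:
    """Safety angle (degrees) of one safety point about the implant axis.

    Within the plane spanned by ``E - I`` and ``S - I``, SafA = alpha - beta
    where ``alpha`` is the angle between the implant axis and the line I-S,
    and ``beta = arcsin(r / |S - I|)`` is the half-angle subtended from I by
    the circle of implant radius ``r`` about ``S`` (i.e. the angle to the
    tangent line).  A negative result means the corridor is narrower than
    the implant; it is returned unclamped.

    Raises :class:`TangentUndefinedError` when ``|S - I| <= r``.
    """
    I, E, S = _as_point(I), _as_point(E), _as_point(S)
    ie = E - I
    nie = np.linalg.norm(ie)
    if nie == 0.0:
        raise UndefinedDirectionError("zero-length implant axis")
    si = S - I
    nsi = np.linalg.norm(si)
    if nsi <= r:
        raise TangentUndefinedError(
            f"|S - I| = {nsi:.4g} mm <= r = {r:.4g} mm: no tangent from I"
        )
    cos_alpha = np.clip(np.dot(ie, si) / (nie * nsi), -1.0, 1.0)
    alpha = np.arccos(cos_alpha)
    beta = np.arcsin(r / nsi) if r > 0 else 0.0
    if alpha == 0.0:
        warnings.warn("safety point lies on the implant axis",
                      CollinearSafetyPointWarning, stacklevel=2)
    return float(np.degrees(alpha - beta))


def corridor_width(implant: ImplantAxis, S_pair, r: float = 0.0) -> float:
    """Corridor width (mm) in the plane of one safety-point pair.

    The width is the sum of the perpendicular distances of the two opposing
    safety points to the implant axis, measured within their common plane
    (the implant radius enters SafA only, not the width).  If both points
    fall on the same side of the axis the overlap is returned as a
    non-positive value rather than clamped, signalling a degenerate pair.
    """
    Sa, Sb = (_as_point(s) for s in S_pair)
    u = implant.direction
    I = implant.insertion_I
    # in-plane unit normal from the first safety point's offset
    wa = Sa - I
    wa_perp = wa - np.dot(wa, u) * u
    da = np.linalg.norm(wa_perp)
    if da == 0.0:
        # first point on the axis: try the second as normal reference
        wb = Sb - I
        wb_perp = wb - np.dot(wb, u) * u
        return float(np.linalg.norm(wb_perp))
    n = wa_perp / da
    wb = Sb - I
    db = float(np.dot(wb - np.dot(wb, u) * u, n))  # signed offset of Sb along n
    if db < 0.0:
        return float(da - db)          # opposite sides: distances add
    return float(-(abs(da - db)) if da != db else 0.0)


def _plane_normal(implant: ImplantAxis, S) -> np.ndarray:
    u = implant.direction
    w = _as_point(S) - implant.insertion_I
    n = np.cross(u, w)
    nn = np.linalg.norm(n)
    return n / nn if nn > 0 else n


def safety_angles(implant: ImplantAxis, margins: SafetyMargins) -> SafetyAngles:
    """All four safety angles, both corridor widths and the implant length.

    Safety points are grouped (S1, S2) and (S3, S4) as the two pairs lying
    in two planes through the implant axis; a warning is issued when those
    planes deviate from orthogonality by more than 5 degrees.
    """
    I, E = implant.insertion_I, implant.exit_E
    r = margins.implant_radius_r
    sas = [safety_angle(I, E, S, r) for S in margins.points]
    n1 = _plane_normal(implant, margins.S1)
    n2 = _plane_normal(implant, margins.S3)
    if np.linalg.norm(n1) > 0 and np.linalg.norm(n2) > 0:
        dihedral = np.degrees(np.arccos(np.clip(abs(np.dot(n1, n2)), 0.0, 1.0)))
        if dihedral < 85.0:
            warnings.warn(
                f"safety planes deviate from orthogonality by {90 - dihedral:.1f} deg",
                NonOrthogonalPlanesWarning, stacklevel=2)
    w1 = corridor_width(implant, (margins.S1, margins.S2), r)
    w2 = corridor_width(implant, (margins.S3, margins.S4), r)
    flags = tuple(f"saf_a{i + 1}" for i, a in enumerate(sas) if a < 0)
    return SafetyAngles(saf_a1=sas[0], saf_a2=sas[1], saf_a3=sas[2], saf_a4=sas[3],
                        width_plane1=w1, width_plane2=w2,
                        implant_length=implant.length, negative_flags=flags)


# --------------------------------------------------------------------------
# centered axes of simplified corridor shapes

@dataclass(frozen=True)
class CorridorShape:
    """A simplified bone-corridor shape defined by labelled points.

    ``kind`` is ``pyramid`` (labels: one ``apex``, >= 3 ``base``),
    ``prism`` (>= 3 ``face1`` and >= 3 ``face2``) or ``hemi_ellipsoid``
    (>= 9 ``surface`` samples and >= 1 ``base`` point).
    """

    kind: str
    defining_points: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("pyramid", "prism", "hemi_ellipsoid"):
            raise ValueError(f"unknown corridor shape kind {self.kind!r}")
        pts = {k: np.atleast_2d(np.asarray(v, dtype=float))
               for k, v in self.defining_points.items()}
        object.__setattr__(self, "defining_points", pts)


def _fit_ellipsoid_axis(points: np.ndarray) -> np.ndarray:
    """Principal (longest) semi-axis direction of a least-squares ellipsoid.

    Fits the general quadric x'Qx + b'x = 1 and returns the unit
    eigenvector of Q with the smallest positive eigenvalue.
    """
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    D = np.column_stack([x * x, y * y, z * z,
                         2 * x * y, 2 * x * z, 2 * y * z,
                         x, y, z])
    try:
        coef, *_ = np.linalg.lstsq(D, np.ones(len(points)), rcond=None)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise DegenerateShapeError("ellipsoid fit failed") from exc
    a, b, c, d, e, f = coef[:6]
    Q = np.array([[a, d, e], [d, b, f], [e, f, c]])
    evals, evecs = np.linalg.eigh(Q)
    if np.all(evals <= 0) or not np.all(np.isfinite(evals)):
        raise DegenerateShapeError("degenerate ellipsoid fit (non-elliptic quadric)")
    pos = np.where(evals > 0)[0]
    principal = pos[np.argmin(evals[pos])]  # smallest eigenvalue = longest axis
    return evecs[:, principal]


def centered_axis(shape: CorridorShape) -> tuple[np.ndarray, np.ndarray]:
    """Centered axis (point, unit direction) of a simplified corridor shape.

    * pyramid: line through the apex and the base-polygon centroid,
      directed apex -> base;
    * prism: line through the two end-face centroids, face1 -> face2;
    * hemi-ellipsoid: principal semi-axis direction of the least-squares
      ellipsoid fit through the base-plane centroid, directed away from the
      surface-sample centroid side (base -> dome).
    """
    pts = shape.defining_points
    if shape.kind == "pyramid":
        if "apex" not in pts or "base" not in pts or len(pts["base"]) < 3:
            raise DegenerateShapeError("pyramid needs one apex and >= 3 base points")
        apex = pts["apex"][0]
        base_c = pts["base"].mean(axis=0)
        d = base_c - apex
        n = np.linalg.norm(d)
        if n <= 1e-12:
            raise DegenerateShapeError("pyramid apex coincides with base centroid")
        base_span = pts["base"] - base_c
        if np.linalg.matrix_rank(base_span, tol=1e-9) < 2:
            raise DegenerateShapeError("pyramid base polygon is degenerate")
        return apex, d / n
    if shape.kind == "prism":
        if len(pts.get("face1", ())) < 3 or len(pts.get("face2", ())) < 3:
            raise DegenerateShapeError("prism needs >= 3 points per end face")
        c1 = pts["face1"].mean(axis=0)
        c2 = pts["face2"].mean(axis=0)
        d = c2 - c1
        n = np.linalg.norm(d)
        if n <= 1e-12:
            raise DegenerateShapeError("prism end-face centroids coincide")
        return c1, d / n
    # hemi_ellipsoid
    if len(pts.get("surface", ())) < 9 or "base" not in pts:
        raise DegenerateShapeError(
            "hemi-ellipsoid needs >= 9 surface samples and base points")
    axis_dir = _fit_ellipsoid_axis(pts["surface"])
    base_c = pts["base"].mean(axis=0)
    dome_c = pts["surface"].mean(axis=0)
    if np.dot(axis_dir, dome_c - base_c) < 0:
        axis_dir = -axis_dir
    return base_c, axis_dir


def simulate_optimal_implant(axis: tuple, ventral_surface_points,
                             far_boundary_points,
                             site: SiteDescriptor | None = None) -> ImplantAxis:
    """Place insertion and exit points on a centered axis.

    The insertion point is the point of the axis closest to the ventral
    bone-surface sample set; the exit point the one closest to the far
    corridor boundary set.  If the boundary sets are given in the wrong
    order relative to the axis direction the segment is reoriented so that
    insertion precedes exit.
    """
    p0, u = (_as_point(axis[0]),
             np.asarray(axis[1], dtype=float) / np.linalg.norm(axis[1]))

    def _closest_param(point_set):
        pts = np.atleast_2d(np.asarray(point_set, dtype=float))
        if len(pts) == 0:
            raise ValueError("boundary point set is empty")
        t = (pts - p0) @ u
        foot = p0 + t[:, None] * u
        d = np.linalg.norm(pts - foot, axis=1)
        return float(t[np.argmin(d)])

    t_i = _closest_param(ventral_surface_points)
    t_e = _closest_param(far_boundary_points)
    if t_i == t_e:
        raise ZeroLengthImplantError(
            "boundary sets project to the same axis position")
    I = p0 + t_i * u
    E = p0 + t_e * u
    return ImplantAxis(insertion_I=I, exit_E=E,
                       site_id=site.site_id if site else "",
                       frame_ref=site.frame if site else "C2")
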