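"""Independent brute-force constructions used to check the geometry.

These deliberately avoid the formulas used by the implementation: angles
are measured by explicit projection and normalized dot products, tangency
by root-finding on a rotating ray, and widths by 2D computational geometry
in the safety-point plane.
"""

import numpy as np
from scipy.optimize import brentq

_AXES = np.eye(3)  # anatomical x (craniocaudal), y (mediolateral), z (ventrodorsal)


def projection_angle_oracle(v, plane: str) -> float:
    """Signed angle between the projection of v onto a plane and its
    reference axis, measured via normalized dot product (degrees)."""
    v = np.asarray(v, dtype=float)
    ref, other = {
        "sagittal": (_AXES[0], _AXES[2]),    # x-z plane, reference x
        "dorsal": (_AXES[0], _AXES[1]),      # x-y plane, reference x
        "transverse": (_AXES[2], _AXES[1]),  # z-y plane, reference z
    }[plane]
    normal = np.cross(ref, other)
    proj = v - np.dot(v, normal) * normal
    n = np.linalg.norm(proj)
    if n == 0:
        raise ValueError("projection vanishes")
    cosang = np.clip(np.dot(proj, ref) / n, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return float(ang if np.dot(proj, other) >= 0 else -ang)


def tangent_angle_oracle(I, E, S, r) -> float:
    """Safety angle by rotating a ray from I toward S until it becomes
    tangent to the circle of radius r about S (root finding on the
    point-to-ray distance)."""
    I, E, S = (np.asarray(p, dtype=float) for p in (I, E, S))
    u = (E - I) / np.linalg.norm(E - I)
    w = S - I
    w_perp = w - np.dot(w, u) * u
    alpha = np.arccos(np.clip(np.dot(u, w / np.linalg.norm(w)), -1, 1))
    if r == 0:
        return float(np.degrees(alpha))
    if np.linalg.norm(w_perp) == 0:
        return float(np.degrees(-np.arcsin(r / np.linalg.norm(w))))
    e2 = w_perp / np.linalg.norm(w_perp)

    def ray_distance(phi):
        d = np.cos(phi) * u + np.sin(phi) * e2
        t = max(np.dot(w, d), 0.0)
        return np.linalg.norm(w - t * d)

    # rotate from the axis (phi=0) toward S (phi=alpha): first tangency
    phi_star = brentq(lambda p: ray_distance(p) - r, 0.0 if ray_distance(0) > r
                      else -np.pi / 2, alpha, xtol=1e-12)
    return float(np.degrees(phi_star))


def planar_width_oracle(I, E, Sa, Sb) -> float:
    """Corridor width by 2D geometry in the safety-pair plane: signed
    perpendicular offsets of both points from the axis line."""
    I, E, Sa, Sb = (np.asarray(p, dtype=float) for p in (I, E, Sa, Sb))
    u = (E - I) / np.linalg.norm(E - I)
    wa = Sa - I
    perp = wa - np.dot(wa, u) * u
    if np.linalg.norm(perp) == 0:
        wb = Sb - I
        return float(np.linalg.norm(wb - np.dot(wb, u) * u))
    n = perp / np.linalg.norm(perp)
    # 2D coordinates (along axis, along n)
    sa = np.dot(Sa - I, n)
    sb = np.dot(Sb - I, n)
    if sa * sb < 0:
        return float(abs(sa) + abs(sb))
    return float(-abs(abs(sa) - abs(sb)))
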