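"""3D geometry primitives and dynamic area-of-interest (AOI) hit-testing.

Coordinate frame (fixed for the whole package): right-handed, metres,
y-up, origin at the centre of the tabletop surface.  The two agents sit
on opposite sides of the table along the z axis; the three task cubes
lie in a row along x at z = 0.

AOI semantics
-------------
* The *face* AOI is angular: a gaze sample is a face look when the gaze
  ray lies within ``face_radius_deg`` of visual angle of the partner's
  nasion (default 7.5 deg).  The face test has absolute precedence.
* All other AOIs (hand, body, cubes, start cubes) are solids; a sample
  hits the box whose ray entry point is nearest along the gaze ray.
  Entry-distance ties are broken by the fixed precedence
  hand > cube > start > body.
* ``other`` when nothing is hit.  Invalid tracker samples are labelled
  ``other`` and must be masked by the caller via the validity flag;
  they are never counted as looks downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AOI_LABELS",
    "AoiLayout",
    "visual_angle",
    "ray_aabb_entry",
    "ray_obb_entry",
    "hand_box_frame",
    "classify_gaze_sample",
    "classify_gaze_stream",
    "default_layout",
]

#: Canonical label order; integer codes index into this tuple.
AOI_LABELS = ("face", "hand", "cube1", "cube2", "cube3", "start", "body", "other")

_EPS = 1e-12


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"{name} must have 3 components, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def normalize(v: np.ndarray) -> np.ndarray:
    """Unit-normalize the last axis; raises on (near-)zero vectors."""
    a = _as_vec3(v)
    n = np.linalg.norm(a, axis=-1, keepdims=True)
    if np.any(n < 1e-9):
        raise ValueError("cannot normalize a zero-length vector")
    return a / n


def visual_angle(origin, direction, point) -> float:
    """Angle in degrees between a gaze ray and the origin->point vector.

    Parameters
    ----------
    origin : (3,) array-like
        Gaze origin (cyclopean eye position), metres.
    direction : (3,) array-like
        Unit gaze direction.
    point : (3,) array-like
        Target point, metres.  Must differ from ``origin``.

    Returns
    -------
    float
        Angle in ``[0, 180]`` degrees.
    """
    o = _as_vec3(origin, "origin")
    d = _as_vec3(direction, "direction")
    p = _as_vec3(point, "point")
    v = p - o
    nv = np.linalg.norm(v)
    if nv < 1e-9:
        raise ValueError("point coincides with gaze origin; visual angle undefined")
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        raise ValueError("gaze direction has zero norm")
    cosang = float(np.dot(d / nd, v / nv))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _visual_angle_stream(origins, dirs, points) -> np.ndarray:
    """Vectorized visual angle, degrees. origins/dirs (N,3), points (N,3) or (3,)."""
    v = np.broadcast_to(points, origins.shape) - origins
    nv = np.linalg.norm(v, axis=-1)
    nd = np.linalg.norm(dirs, axis=-1)
    cos = np.einsum("ij,ij->i", dirs, v) / np.maximum(nv * nd, _EPS)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def ray_aabb_entry(origins, dirs, lo, hi) -> np.ndarray:
    """Entry distance of rays into an axis-aligned box (slab method).

    Returns the parametric distance ``t >= 0`` of the first intersection
    with the box ``[lo, hi]`` for each ray, or ``inf`` when the ray
    misses the box.  A ray starting inside the box has entry ``0``.
    Accepts (N,3) or (3,) inputs.
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d
        t1 = (lo - o) * inv
        t2 = (hi - o) * inv
    # parallel rays: slab constraint reduces to origin-in-slab; an
    # origin outside the slab forces a miss (both bounds +inf so that
    # tnear = +inf > tfar)
    par = np.abs(d) < _EPS
    inside = (o >= lo) & (o <= hi)
    t1 = np.where(par, np.where(inside, -np.inf, np.inf), t1)
    t2 = np.where(par, np.where(inside, np.inf, np.inf), t2)
    tnear = np.max(np.minimum(t1, t2), axis=-1)
    tfar = np.min(np.maximum(t1, t2), axis=-1)
    hit = (tfar >= tnear) & (tfar >= 0)
    entry = np.where(hit, np.maximum(tnear, 0.0), np.inf)
    return entry if np.ndim(origins) > 1 else float(entry[0])


def _orthonormal_frame(axis: np.ndarray) -> np.ndarray:
    """Rotation matrices (..., 3, 3) whose first row is ``axis`` (unit)."""
    u = axis
    # pick the global axis least aligned with u as helper
    helper = np.zeros_like(u)
    idx = np.argmin(np.abs(u), axis=-1)
    np.put_along_axis(helper, idx[..., None], 1.0, axis=-1)
    v = np.cross(u, helper)
    v = v / np.maximum(np.linalg.norm(v, axis=-1, keepdims=True), _EPS)
    w = np.cross(u, v)
    return np.stack([u, v, w], axis=-2)


def hand_box_frame(wrist, fingertip, length: float = 0.20, cross: float = 0.10):
    """Pose of the hand AOI box from wrist and fingertip positions.

    The box is an oriented 10 x 20 cm solid (square 10 cm cross-section)
    that begins at the wrist and extends ``length`` metres toward the
    index fingertip, re-posed every frame.

    Returns ``(center, rot, half_extents)`` with ``rot`` rows = box axes.
    """
    w = np.atleast_2d(np.asarray(wrist, dtype=float))
    f = np.atleast_2d(np.asarray(fingertip, dtype=float))
    axis = f - w
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    axis = np.where(n > 1e-9, axis / np.maximum(n, _EPS), [[1.0, 0.0, 0.0]])
    rot = _orthonormal_frame(axis)
    center = w + axis * (length / 2.0)
    half = np.array([length / 2.0, cross / 2.0, cross / 2.0])
    return center, rot, half


def ray_obb_entry(origins, dirs, center, rot, half) -> np.ndarray:
    """Entry distance into an oriented box; rotates rays into the box frame."""
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    c = np.atleast_2d(np.asarray(center, dtype=float))
    r = np.asarray(rot, dtype=float)
    if r.ndim == 2:
        r = r[None, :, :]
    ol = np.einsum("nij,nj->ni", r, np.broadcast_to(o - c, (max(len(o), len(c)), 3)))
    dl = np.einsum("nij,nj->ni", np.broadcast_to(r, (max(len(o), len(r)), 3, 3)), d)
    entry = ray_aabb_entry(ol, dl, -half, half)
    return entry if np.ndim(origins) > 1 else float(np.atleast_1d(entry)[0])


@dataclass
class AoiLayout:
    """Scene AOI geometry, resolved for one agent at one time (or stream).

    All positions in metres.  ``partner_nasion`` / ``partner_wrist`` /
    ``partner_fingertip`` may be (3,) for a static pose or (N,3) for a
    per-frame stream aligned with the gaze samples being classified.
    """

    partner_nasion: np.ndarray
    cube_centers: np.ndarray  # (3, 3): cube1..cube3
    face_radius_deg: float = 7.5
    cube_size: float = 0.10
    start_centers: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3))
    )  # one 5 cm start cube per agent
    start_size: float = 0.05
    body_center: np.ndarray | None = None
    body_size: tuple[float, float, float] = (0.40, 0.60, 0.15)  # w x h x depth
    partner_wrist: np.ndarray | None = None
    partner_fingertip: np.ndarray | None = None
    hand_length: float = 0.20
    hand_cross: float = 0.10

    def __post_init__(self):
        self.partner_nasion = np.asarray(self.partner_nasion, dtype=float)
        self.cube_centers = np.asarray(self.cube_centers, dtype=float)
        if self.cube_centers.shape != (3, 3):
            raise ValueError("exactly 3 cube AOIs are required (shape (3, 3))")
        self.start_centers = np.asarray(self.start_centers, dtype=float).reshape(-1, 3)

    def cube_bounds(self):
        h = self.cube_size / 2.0
        return self.cube_centers - h, self.cube_centers + h

    def start_bounds(self):
        h = self.start_size / 2.0
        return self.start_centers - h, self.start_centers + h

    def body_bounds(self):
        if self.body_center is None:
            return None
        half = np.array(self.body_size, dtype=float) / 2.0
        # body box spans width (x) by height (y) by depth (z) in world axes
        return self.body_center - half, self.body_center + half


def classify_gaze_stream(origins, dirs, layout: AoiLayout, valid=None) -> np.ndarray:
    """Label every gaze sample with exactly one AOI.

    Parameters
    ----------
    origins, dirs : (N, 3) arrays
        Gaze ray origins and (not necessarily unit) directions.
    layout : AoiLayout
        Scene geometry; dynamic fields may be per-frame (N,3).
    valid : (N,) bool array, optional
        Tracker validity; invalid samples are labelled ``other``.

    Returns
    -------
    ndarray of str
        One of :data:`AOI_LABELS` per sample.
    """
    o = np.atleast_2d(np.asarray(origins, dtype=float))
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    n = len(o)
    labels = np.full(n, "other", dtype=object)

    # face: angular criterion, absolute precedence (boundary inclusive)
    ang = _visual_angle_stream(o, d, layout.partner_nasion)
    is_face = ang <= layout.face_radius_deg

    # box entries; order encodes tie-break precedence: hand > cube > start > body
    entries = []
    names = []
    if layout.partner_wrist is not None and layout.partner_fingertip is not None:
        c, r, h = hand_box_frame(
            layout.partner_wrist, layout.partner_fingertip, layout.hand_length, layout.hand_cross
        )
        entries.append(np.atleast_1d(ray_obb_entry(o, d, c, r, h)))
        names.append("hand")
    lo, hi = layout.cube_bounds()
    for i in range(3):
        entries.append(np.atleast_1d(ray_aabb_entry(o, d, lo[i], hi[i])))
        names.append(f"cube{i + 1}")
    slo, shi = layout.start_bounds()
    for i in range(len(layout.start_centers)):
        entries.append(np.atleast_1d(ray_aabb_entry(o, d, slo[i], shi[i])))
        names.append("start")
    bb = layout.body_bounds()
    if bb is not None:
        entries.append(np.atleast_1d(ray_aabb_entry(o, d, bb[0], bb[1])))
        names.append("body")

    if entries:
        ent = np.stack(entries, axis=0)  # (k, N)
        best = np.argmin(ent, axis=0)  # argmin takes first minimum -> precedence order
        hit = np.isfinite(ent[best, np.arange(n)])
        for k, name in enumerate(names):
            sel = hit & (best == k)
            labels[sel] = name
    labels[is_face] = "face"
    if valid is not None:
        labels[~np.asarray(valid, dtype=bool)] = "other"
    return labels.astype(str)


def classify_gaze_sample(origin, direction, layout: AoiLayout, valid: bool = True) -> str:
    """Classify a single gaze sample; see :func:`classify_gaze_stream`."""
    if not valid:
        return "other"
    return str(classify_gaze_stream(np.asarray(origin)[None], np.asarray(direction)[None], layout)[0])


def default_layout(for_agent: int = 0, cube_spacing: float = 0.30, **kw) -> AoiLayout:
    """The study scene as seen by ``for_agent`` (0 or 1).

    Agents face each other across the table (z axis); agent 0 sits at
    negative z.  Three 10 cm cubes lie along x at z = 0, ``cube_spacing``
    apart; a 5 cm start cube sits near each agent's right hand.
    """
    from .scene import agent_nasion, body_center, cube_centers, start_center

    other = 1 - for_agent
    return AoiLayout(
        partner_nasion=agent_nasion(other),
        cube_centers=cube_centers(cube_spacing),
        start_centers=np.stack([start_center(0), start_center(1)]),
        body_center=body_center(other),
        **kw,
    )
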