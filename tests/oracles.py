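"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the package's slab/ray-intersection code paths:
AOI membership is decided by dense point-marching along each ray with
point-in-box tests, refined by bisection (valid because a convex body's
intersection with a ray is a single interval).
"""

import numpy as np

from dyadgaze import scene
from dyadgaze.geometry import hand_box_frame, normalize, visual_angle


def scalar_oracle_label(origin, direction, layout, step=5e-4, t_max=4.0):
    """Pure-Python reference oracle for a single gaze ray."""
    if visual_angle(origin, direction, layout.partner_nasion) <= layout.face_radius_deg:
        return "face"
    boxes = _boxes(layout)
    d = normalize(direction)
    ts = np.arange(0.0, t_max, step)
    entries = []
    for k, (name, inside) in enumerate(boxes):
        for t in ts:
            if inside(origin + t * d):
                lo_t, hi_t = max(t - step, 0.0), t
                for _ in range(60):
                    mid = 0.5 * (lo_t + hi_t)
                    if inside(origin + mid * d):
                        hi_t = mid
                    else:
                        lo_t = mid
                entries.append((hi_t if t > 0 else 0.0, k, name))
                break
    if not entries:
        return "other"
    entries.sort()
    return entries[0][2]


def _boxes(layout):
    boxes = []
    if layout.partner_wrist is not None:
        c, r, h = hand_box_frame(layout.partner_wrist, layout.partner_fingertip,
                                 layout.hand_length, layout.hand_cross)
        c, r = np.asarray(c)[0], np.asarray(r)[0]

        def _in_hand(p, c=c, r=r, h=h):
            return bool(np.all(np.abs(r @ (p - c)) <= h))

        boxes.append(("hand", _in_hand))
    lo, hi = layout.cube_bounds()
    for i in range(3):
        boxes.append((f"cube{i+1}",
                      lambda p, lo=lo[i], hi=hi[i]: bool(np.all(p >= lo) and np.all(p <= hi))))
    slo, shi = layout.start_bounds()
    for i in range(len(layout.start_centers)):
        boxes.append(("start",
                      lambda p, lo=slo[i], hi=shi[i]: bool(np.all(p >= lo) and np.all(p <= hi))))
    bb = layout.body_bounds()
    if bb is not None:
        boxes.append(("body",
                      lambda p, lo=bb[0], hi=bb[1]: bool(np.all(p >= lo) and np.all(p <= hi))))
    return boxes


def _entry_times_aabb(origins, dirs, lo, hi, ts):
    """(N,) entry distances by marching + bisection for one AABB."""
    pts = origins[:, None, :] + ts[None, :, None] * dirs[:, None, :]
    inside = np.all((pts >= lo) & (pts <= hi), axis=2)  # (N, T)
    return _refine(origins, dirs, inside, ts,
                   lambda p, sel: np.all((p >= lo) & (p <= hi), axis=-1))


def _entry_times_obb(origins, dirs, center, rot, half, ts):
    """(N,) entry distances for per-config oriented boxes."""
    pts = origins[:, None, :] + ts[None, :, None] * dirs[:, None, :]
    q = np.einsum("nij,ntj->nti", rot, pts - center[:, None, :])
    inside = np.all(np.abs(q) <= half, axis=2)

    def member(p, sel):  # p: one point per selected config
        q = np.einsum("nij,nj->ni", rot[sel], p - center[sel])
        return np.all(np.abs(q) <= half, axis=-1)

    return _refine(origins, dirs, inside, ts, member)


def _refine(origins, dirs, inside, ts, member):
    n = len(origins)
    entry = np.full(n, np.inf)
    any_hit = inside.any(axis=1)
    idx = np.argmax(inside, axis=1)
    hit0 = any_hit & (idx == 0)
    entry[hit0] = 0.0
    todo = any_hit & (idx > 0)
    if todo.any():
        sel = np.flatnonzero(todo)
        lo_t = ts[idx[sel] - 1]
        hi_t = ts[idx[sel]]
        o, d = origins[sel], dirs[sel]
        for _ in range(60):
            mid = 0.5 * (lo_t + hi_t)
            m = member(o + mid[:, None] * d, sel)
            hi_t = np.where(m, mid, hi_t)
            lo_t = np.where(m, lo_t, mid)
        entry[sel] = hi_t
    return entry


def batch_oracle_labels(origins, dirs, agents, wrists, tips, layout_kw=None,
                        step=5e-4, t_max=4.0, chunk=250):
    """Vectorized marching oracle over many configurations.

    ``agents`` selects whose scene view applies per config; ``wrists`` /
    ``tips`` pose the partner's hand box per config.
    """
    from dyadgaze.geometry import default_layout

    layout_kw = layout_kw or {}
    n = len(origins)
    out = np.empty(n, dtype=object)
    ts = np.arange(0.0, t_max, step)
    for agent in (0, 1):
        sel = np.flatnonzero(np.asarray(agents) == agent)
        layout = default_layout(for_agent=agent, **layout_kw)
        for s in range(0, len(sel), chunk):
            ii = sel[s:s + chunk]
            o, d = origins[ii], dirs[ii]
            c, r, h = hand_box_frame(wrists[ii], tips[ii],
                                     layout.hand_length, layout.hand_cross)
            entries = [("hand", _entry_times_obb(o, d, np.asarray(c), np.asarray(r),
                                                 np.asarray(h), ts))]
            lo, hi = layout.cube_bounds()
            for i in range(3):
                entries.append((f"cube{i+1}", _entry_times_aabb(o, d, lo[i], hi[i], ts)))
            slo, shi = layout.start_bounds()
            for i in range(len(layout.start_centers)):
                entries.append(("start", _entry_times_aabb(o, d, slo[i], shi[i], ts)))
            bb = layout.body_bounds()
            entries.append(("body", _entry_times_aabb(o, d, bb[0], bb[1], ts)))

            names = [nm for nm, _ in entries]
            ent = np.stack([e for _, e in entries], axis=0)  # (k, m)
            best = np.argmin(ent, axis=0)
            hit = np.isfinite(ent[best, np.arange(len(ii))])
            labels = np.where(hit, np.array(names, dtype=object)[best], "other")
            # face overrides everything
            nas = layout.partner_nasion
            v = nas[None, :] - o
            cos = np.einsum("ij,ij->i", d, v) / np.maximum(
                np.linalg.norm(v, axis=1) * np.linalg.norm(d, axis=1), 1e-12)
            ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            labels[ang <= layout.face_radius_deg] = "face"
            out[ii] = labels
    return out.astype(str)


def sample_configs(n, rng):
    """Scene-realistic random gaze/hand configurations for oracle sweeps."""
    agents = rng.integers(0, 2, size=n)
    side = np.where(agents == 0, 1.0, -1.0)  # partner side of the table
    origins = np.stack([scene.agent_eye_origin(a) for a in agents]) \
        + rng.normal(0, 0.02, (n, 3))
    aims = np.column_stack([rng.uniform(-0.8, 0.8, n),
                            rng.uniform(-0.1, 0.7, n),
                            rng.uniform(-0.8, 0.8, n)])
    dirs = normalize(aims - origins)
    wrists = np.column_stack([rng.normal(0, 0.15, n),
                              rng.normal(0.1, 0.15, n),
                              rng.normal(0.3 * side, 0.15)])
    tips = wrists + normalize(rng.normal(size=(n, 3))) * 0.25
    return origins, dirs, agents, wrists, tips
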