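"""Low-level geometric primitives shared by synthesis and homogenization."""

from __future__ import annotations

import numpy as np

__all__ = ["clip_segments_to_ball", "segment_segment_closest_points", "disk_disk_overlap_area"]


def clip_segments_to_ball(x1, x2, center, radius):
    """Parameter interval of each segment inside a ball.

    Segments are parameterized as g(s) = (1-s) x1 + s x2, s in [0,1].
    Returns ``(s_lo, s_hi, inside)`` where ``inside`` is False for
    segments that miss the ball (tangency counts as a miss: the chord has
    zero length).  Works for any dimension of the input points.

    Vectorized over an (n, d) stack of segments.
    """
    x1 = np.atleast_2d(np.asarray(x1, float))
    x2 = np.atleast_2d(np.asarray(x2, float))
    c = np.asarray(center, float)
    d = x2 - x1
    f = x1 - c
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", d, f)
    cc = np.einsum("ij,ij->i", f, f) - radius**2

    s_lo = np.zeros(len(x1))
    s_hi = np.zeros(len(x1))
    inside = np.zeros(len(x1), dtype=bool)

    deg = a <= 0.0  # zero-length segments: a point has no chord
    disc = b * b - 4.0 * a * cc
    ok = (~deg) & (disc > 0.0)
    if np.any(ok):
        sq = np.sqrt(disc[ok])
        lo = (-b[ok] - sq) / (2.0 * a[ok])
        hi = (-b[ok] + sq) / (2.0 * a[ok])
        lo = np.clip(lo, 0.0, 1.0)
        hi = np.clip(hi, 0.0, 1.0)
        good = hi > lo
        idx = np.flatnonzero(ok)[good]
        s_lo[idx] = lo[good]
        s_hi[idx] = hi[good]
        inside[idx] = True
    return s_lo, s_hi, inside


def segment_segment_closest_points(p1, q1, p2, q2):
    """Closest points between two stacks of 3D line segments.

    Implements the standard clamped quadratic minimization (robust for
    parallel and degenerate point segments).  Returns ``(c1, c2, dist)``.
    """
    p1 = np.atleast_2d(np.asarray(p1, float))
    q1 = np.atleast_2d(np.asarray(q1, float))
    p2 = np.atleast_2d(np.asarray(p2, float))
    q2 = np.atleast_2d(np.asarray(q2, float))
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b

    s = np.zeros(len(p1))
    nondeg = denom > 1e-30 * np.maximum(a * e, 1e-300)
    s[nondeg] = np.clip((b * f - c * e)[nondeg] / denom[nondeg], 0.0, 1.0)
    # parallel case: any s works, keep 0 and let t clamp

    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(e > 0, (b * s + f) / np.where(e > 0, e, 1.0), 0.0)

    # clamp t then recompute s
    t = np.clip(t, 0.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(a > 0, (b * t - c) / np.where(a > 0, a, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    # one more t update for the corner cases where s got clamped
    t = np.where(e > 0, (b * s + f) / np.where(e > 0, e, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)

    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2
    return c1, c2, np.linalg.norm(c1 - c2, axis=1)


def disk_disk_overlap_area(r1: float, r2: float, d: float) -> float:
    """Area of the intersection of two disks with radii r1, r2 at center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return np.pi * r * r
    a1 = r1 * r1 * np.arccos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * np.arccos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    k = 0.5 * np.sqrt(
        (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2)
    )
    return a1 + a2 - k
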