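"""Rider joint kinematics: limb distances and the elbow angle.

The elbow angle is the interior angle at the elbow of the triangle formed
by shoulder, elbow and wrist markers, obtained from the law of cosines on
the pairwise Euclidean distances.  The same construction applies to any
three markers (knee, backbone, ...); only the elbow is named here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["JointTriple", "TriangleSides", "side_lengths", "elbow_angle",
           "DegenerateGeometryError"]


class DegenerateGeometryError(ValueError):
    """Vertex coincident with an endpoint: the angle is undefined."""


@dataclass(frozen=True)
class JointTriple:
    """Three 3-D marker positions: A and C are the distal points (wrist,
    shoulder), B is the vertex (elbow)."""

    A: tuple[float, float, float]
    B: tuple[float, float, float]
    C: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("A", "B", "C"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise ValueError(f"point {name} must be 3 finite coordinates")


@dataclass(frozen=True)
class TriangleSides:
    """Side lengths of the marker triangle: a = |BC|, b = |CA|, c = |AB|."""

    a: float
    b: float
    c: float


def side_lengths(t: JointTriple) -> TriangleSides:
    """Pairwise Euclidean distances between the three markers."""
    A, B, C = (np.asarray(p, dtype=float) for p in (t.A, t.B, t.C))
    return TriangleSides(
        a=float(np.linalg.norm(B - C)),
        b=float(np.linalg.norm(C - A)),
        c=float(np.linalg.norm(A - B)),
    )


def elbow_angle(t: JointTriple) -> float:
    """Interior angle at the vertex B, in degrees.

    Law of cosines: ``angle = arccos((c^2 + a^2 - b^2) / (2 c a))`` with
    c = |AB|, a = |BC|, b = |CA|.  The arccos argument is clamped to
    [-1, 1] so exactly collinear markers return 0 or 180 rather than a
    domain error.

    Raises
    ------
    DegenerateGeometryError
        If B coincides with A or C (a zero-length limb).
    """
    s = side_lengths(t)
    if s.a == 0.0 or s.c == 0.0:
        raise DegenerateGeometryError(
            "vertex B coincides with an endpoint; elbow angle undefined"
        )
    cos_b = (s.c**2 + s.a**2 - s.b**2) / (2.0 * s.c * s.a)
    cos_b = min(1.0, max(-1.0, cos_b))
    return float(np.degrees(np.arccos(cos_b)))
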