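"""Normalized-frame geometry of the triad and the guarding circle.

Each frame of a triad is mapped by an orientation-preserving similarity
transform (translation + rotation + uniform scaling) into a frame where
the female sits at (0, 0) and the reference (rival) male at (1, 0).  In
that frame the "guarding circle" is the disc of center (1/2, 0) and
radius 1/2.  By Thales' theorem the focal male lies inside this circle
exactly when he sees the female and the rival at an obtuse angle — the
geometric signature of interposing himself between them.  Membership is
therefore computable two independent ways (circle inequality in the
normalized frame, dot-product sign in raw coordinates) and the two must
always agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectories import TriadRecording

__all__ = [
    "RelativePosition",
    "NearFarAssignment",
    "ClassificationError",
    "to_relative_frame",
    "relative_positions",
    "in_guarding_circle",
    "obtuse_angle_oracle",
    "classify_near_far",
    "relative_position_table",
]


class ClassificationError(ValueError):
    """No complete frame available to classify near/far males."""


@dataclass(frozen=True)
class RelativePosition:
    """Focal male's coordinates in the female=(0,0), rival=(1,0) frame.

    ``valid`` is False when the transform is undefined (female and
    reference coincident, or a fish missing); such frames are excluded
    from all denominators.
    """

    X: float
    Y: float
    frame_index: int = -1
    valid: bool = True


@dataclass(frozen=True)
class NearFarAssignment:
    """Which male is near (smaller mean distance to the female) vs far."""

    near_id: str
    far_id: str
    mean_dist_near: float
    mean_dist_far: float
    tie_broken: bool = False


def to_relative_frame(female, reference_male, focal_male, frame_index: int = -1) -> RelativePosition:
    """Similarity-transform the focal male into the normalized frame.

    With f = reference - female, n = focal - female and D^2 = |f|^2:

        X = (f . n) / D^2          (projection along the female-rival axis)
        Y = (f x n) / D^2          (signed perpendicular offset)

    The transform preserves angles and distance ratios, maps the female
    to (0, 0) and the reference male to (1, 0) exactly, and is undefined
    (valid=False) when female and reference coincide or any coordinate
    is missing.
    """
    female = np.asarray(female, dtype=float)
    reference_male = np.asarray(reference_male, dtype=float)
    focal_male = np.asarray(focal_male, dtype=float)
    if not (
        np.all(np.isfinite(female))
        and np.all(np.isfinite(reference_male))
        and np.all(np.isfinite(focal_male))
    ):
        return RelativePosition(np.nan, np.nan, frame_index, valid=False)
    f = reference_male - female
    n = focal_male - female
    d2 = float(f @ f)
    if d2 == 0.0:
        return RelativePosition(np.nan, np.nan, frame_index, valid=False)
    x = float(f @ n) / d2
    y = float(f[0] * n[1] - f[1] * n[0]) / d2
    return RelativePosition(x, y, frame_index)


def relative_positions(
    female_xy: np.ndarray, reference_xy: np.ndarray, focal_xy: np.ndarray
) -> list[RelativePosition]:
    """Vector version of :func:`to_relative_frame` over aligned frame arrays."""
    return [
        to_relative_frame(f, r, p, frame_index=i)
        for i, (f, r, p) in enumerate(zip(female_xy, reference_xy, focal_xy))
    ]


def in_guarding_circle(rel: RelativePosition) -> bool:
    """True iff the relative position lies in the disc of center (1/2, 0),
    radius 1/2.  The inequality (X - 1/2)^2 + Y^2 <= 1/4 simplifies to
    X^2 + Y^2 <= X.  The boundary (right angle at the focal male) counts
    as inside.
    """
    if not rel.valid:
        raise ValueError("guarding-circle membership undefined for invalid frame")
    return rel.X * rel.X + rel.Y * rel.Y <= rel.X


def obtuse_angle_oracle(female, reference_male, focal_male) -> bool:
    """Raw-coordinate membership check: is the angle at the focal male
    between the female and the reference male non-acute?

    True iff (female - focal) . (reference - focal) <= 0.  A right angle
    (dot product zero) counts True, matching the circle-boundary rule.
    Raises on degenerate input (focal coincident with either other fish).
    """
    female = np.asarray(female, dtype=float)
    reference_male = np.asarray(reference_male, dtype=float)
    focal_male = np.asarray(focal_male, dtype=float)
    u = female - focal_male
    v = reference_male - focal_male
    if float(u @ u) == 0.0 or float(v @ v) == 0.0:
        raise ValueError("angle undefined: focal male coincides with another fish")
    return float(u @ v) <= 0.0


def relative_position_table(
    triad: TriadRecording, focal_id: str, reference_id: str
):
    """Per-frame (time_s, X, Y, inside) debug table for scatter plots.

    Returns a pandas DataFrame; invalid frames carry NaN coordinates and
    a missing ``inside`` entry.  Suitable for plotting the focal male's
    relative positions with the guarding circle overlaid.
    """
    import pandas as pd

    focal = triad.male(focal_id)
    reference = triad.male(reference_id)
    rows = []
    for i, (f, r, p) in enumerate(
        zip(triad.female.positions, reference.positions, focal.positions)
    ):
        rel = to_relative_frame(f, r, p, frame_index=i)
        rows.append(
            {
                "time_s": triad.female.timestamps[i],
                "X": rel.X,
                "Y": rel.Y,
                "inside": in_guarding_circle(rel) if rel.valid else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def classify_near_far(triad: TriadRecording) -> NearFarAssignment:
    """Assign near/far male roles by mean distance to the female.

    Means are taken over grid frames where all three fish are located.
    The male with the smaller mean distance is near; an exact tie is
    broken toward the lexicographically smaller fish_id and flagged.
    """
    mask = triad.complete_frames()
    if not mask.any():
        raise ClassificationError(
            f"trial {triad.trial_id!r}: no frame with all three fish located"
        )
    f_xy = triad.female.positions[mask]
    dists = {}
    for male in (triad.male_a, triad.male_b):
        d = np.linalg.norm(male.positions[mask] - f_xy, axis=1)
        dists[male.fish_id] = float(d.mean())
    (id_a, d_a), (id_b, d_b) = sorted(dists.items())
    if d_a == d_b:
        return NearFarAssignment(id_a, id_b, d_a, d_b, tie_broken=True)
    if d_a < d_b:
        return NearFarAssignment(id_a, id_b, d_a, d_b)
    return NearFarAssignment(id_b, id_a, d_b, d_a)
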