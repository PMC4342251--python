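"""Per-trial guarding index, merged-control construction, and the guarding test.

The guarding index of a focal male is the fraction of retained grid
frames in which he lies inside the guarding circle of the normalized
(female, reference-male) frame.  The guarding test compares near-male
indices between interacting triads and "merged" controls — virtual
triads superimposed from fish recorded in isolation, which carry the
no-interaction null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .geometry import NearFarAssignment, classify_near_far, in_guarding_circle, relative_positions
from .trajectories import FishTrack, TriadRecording

__all__ = [
    "GuardingResult",
    "GuardingTestReport",
    "InsufficientReplicatesError",
    "guarding_index",
    "focal_guarding_index",
    "build_merged_control",
    "permuted_merged_controls",
    "guarding_test",
]


class InsufficientReplicatesError(ValueError):
    """A test group has fewer than two trials."""


@dataclass(frozen=True)
class GuardingResult:
    """Guarding index of one focal male in one trial."""

    trial_id: str
    focal_id: str
    reference_id: str
    n_frames_used: int
    n_in_circle: int
    assignment: NearFarAssignment | None = None

    @property
    def guarding_index(self) -> float:
        return self.n_in_circle / self.n_frames_used

    def __str__(self) -> str:  # "62.6%" style, one decimal as reported
        return f"{100 * self.guarding_index:.1f}%"


@dataclass(frozen=True)
class GuardingTestReport:
    """Two-group comparison of guarding indices (two-sample t-test)."""

    label_1: str
    label_2: str
    indices_1: tuple[float, ...]
    indices_2: tuple[float, ...]
    mean_1: float
    mean_2: float
    sem_1: float
    sem_2: float
    t_statistic: float
    df: float
    p_value: float
    equal_var: bool = True

    def summary(self) -> str:
        return (
            f"{self.label_1}: {100 * self.mean_1:.1f}% ± {100 * self.sem_1:.1f}% "
            f"(n={len(self.indices_1)}) vs "
            f"{self.label_2}: {100 * self.mean_2:.1f}% ± {100 * self.sem_2:.1f}% "
            f"(n={len(self.indices_2)}); t({self.df:g}) = {self.t_statistic:.3f}, "
            f"P = {self.p_value:.4g}"
        )


def focal_guarding_index(
    triad: TriadRecording, focal_id: str, reference_id: str
) -> GuardingResult:
    """Guarding index of ``focal_id`` with ``reference_id`` as the (1,0) rival.

    Frames where any fish is missing or the female/reference coincide are
    excluded from the denominator.
    """
    focal = triad.male(focal_id)
    reference = triad.male(reference_id)
    rels = relative_positions(
        triad.female.positions, reference.positions, focal.positions
    )
    valid = [r for r in rels if r.valid]
    if not valid:
        raise ValueError(f"trial {triad.trial_id!r}: no retained frames")
    n_in = sum(in_guarding_circle(r) for r in valid)
    return GuardingResult(
        trial_id=triad.trial_id,
        focal_id=focal_id,
        reference_id=reference_id,
        n_frames_used=len(valid),
        n_in_circle=int(n_in),
    )


def guarding_index(triad: TriadRecording) -> GuardingResult:
    """Near-male guarding index of a trial.

    The near male (smaller mean distance to the female) is the focal
    fish; the far male is the (1, 0) reference.
    """
    assignment = classify_near_far(triad)
    result = focal_guarding_index(triad, assignment.near_id, assignment.far_id)
    return replace(result, assignment=assignment)


def build_merged_control(
    solo_female: FishTrack,
    solo_male_1: FishTrack,
    solo_male_2: FishTrack,
    trial_id: str = "merged",
    condition: str = "merge",
) -> TriadRecording:
    """Superimpose three independently recorded solo tracks into a virtual triad.

    The component trajectories are used unchanged (no mutation, no
    re-alignment beyond requiring a shared timestamp grid); the result is
    analyzed exactly like a real triad and carries the independence null.
    """
    grids = [solo_female.timestamps, solo_male_1.timestamps, solo_male_2.timestamps]
    if not all(
        len(g) == len(grids[0]) and np.allclose(g, grids[0]) for g in grids[1:]
    ):
        raise ValueError("solo tracks are not on a common timestamp grid")
    tracks = [
        replace(tr, source="merged")
        for tr in (solo_female, solo_male_1, solo_male_2)
    ]
    return TriadRecording(
        trial_id=trial_id,
        female=tracks[0],
        male_a=tracks[1],
        male_b=tracks[2],
        condition=condition,
    )


def permuted_merged_controls(
    triads: list[TriadRecording], seed: int = 0
) -> list[TriadRecording]:
    """Extension: merged controls built by shuffling fish across trials.

    Instead of dedicated solo recordings, each virtual triad takes its
    female, first male, and second male from three different (randomly
    drawn, non-repeating within a slot) trials of ``triads``.  This is
    NOT the standard merged-control construction — fish recorded in a
    real triad were interacting — and is offered only as a
    cross-trial-shuffle null when solo recordings are unavailable.
    """
    if len(triads) < 3:
        raise ValueError("need >=3 trials to shuffle fish across trials")
    rng = np.random.default_rng(seed)
    n = len(triads)
    # derangement-style offsets keep the three slots from the same trial
    f_order = rng.permutation(n)
    a_order = np.roll(f_order, 1)
    b_order = np.roll(f_order, 2)
    out = []
    for k in range(n):
        out.append(
            build_merged_control(
                triads[f_order[k]].female,
                triads[a_order[k]].male_a,
                triads[b_order[k]].male_b,
                trial_id=f"shuffle{k:02d}",
                condition="merge-shuffled",
            )
        )
    return out


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def guarding_test(
    experimental: list[GuardingResult] | list[float],
    merged: list[GuardingResult] | list[float],
    label_1: str = "experimental",
    label_2: str = "merged",
    equal_var: bool = True,
) -> GuardingTestReport:
    """Two-sided two-sample t-test of guarding indices between two groups.

    Equal-variance (Student) by default; ``equal_var=False`` selects the
    Welch variant.  Accepts GuardingResult lists or plain index lists.
    """

    def _indices(group) -> np.ndarray:
        return np.array(
            [g.guarding_index if isinstance(g, GuardingResult) else float(g) for g in group]
        )

    x1, x2 = _indices(experimental), _indices(merged)
    for label, x in ((label_1, x1), (label_2, x2)):
        if len(x) < 2:
            raise InsufficientReplicatesError(
                f"group {label!r} has {len(x)} trial(s); need >=2"
            )
    res = stats.ttest_ind(x1, x2, equal_var=equal_var)
    df = len(x1) + len(x2) - 2 if equal_var else float(res.df)
    return GuardingTestReport(
        label_1=label_1,
        label_2=label_2,
        indices_1=tuple(x1),
        indices_2=tuple(x2),
        mean_1=float(x1.mean()),
        mean_2=float(x2.mean()),
        sem_1=_sem(x1),
        sem_2=_sem(x2),
        t_statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        equal_var=equal_var,
    )
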