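"""Dominance classification across repeated trials, proximity-bias test,
and the dominance/paternity summary.

In a dominance test the two males of a mixed-genotype triad are each
scored as the focal fish with the other as the (1, 0) reference — no
near/far pre-selection — over repeated sessions (6 in the standard
protocol).  The per-male guarding-index series are then compared with an
exact two-sided Mann-Whitney rank-sum test: a significantly higher-mean
male is dominant; no significant difference means the pair is equal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .guarding import GuardingResult, focal_guarding_index
from .trajectories import TriadRecording

__all__ = [
    "DominanceOutcome",
    "ProximityBiasResult",
    "PaternitySummary",
    "PairingError",
    "dominance_indices",
    "mann_whitney_exact",
    "dominance_test",
    "proximity_bias_test",
    "paternity_summary",
]

EXACT_ENUMERATION_MAX_N = 8


class PairingError(ValueError):
    """Index series of unequal length cannot form a dominance test."""


@dataclass(frozen=True)
class DominanceOutcome:
    male_a_id: str
    male_b_id: str
    indices_a: tuple[float, ...]
    indices_b: tuple[float, ...]
    u_statistic: float
    p_value: float
    verdict: str  # "a_dominant" | "b_dominant" | "equal"
    alpha: float = 0.05

    def summary(self) -> str:
        mean_a = 100 * float(np.mean(self.indices_a))
        mean_b = 100 * float(np.mean(self.indices_b))
        return (
            f"{self.male_a_id}: {mean_a:.1f}% vs {self.male_b_id}: {mean_b:.1f}% "
            f"(n = {len(self.indices_a)} trials each); U = {self.u_statistic:g}, "
            f"P = {self.p_value:.4g} -> {self.verdict}"
        )


@dataclass(frozen=True)
class ProximityBiasResult:
    """Chi-square test of which male is closer to the female, pooled over frames."""

    male_a_id: str
    male_b_id: str
    n_frames_a_closer: int
    n_frames_b_closer: int
    n_frames_tied: int
    chi_square: float
    p_value: float


@dataclass(frozen=True)
class PaternitySummary:
    """Per-dominance-class progeny marker percentages with one-way ANOVA."""

    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    group_sems: tuple[float, ...]
    group_ns: tuple[int, ...]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    scheffe_p: Mapping[tuple[str, str], float]


def dominance_indices(triad: TriadRecording) -> tuple[GuardingResult, GuardingResult]:
    """Score each male as focal with the other as the (1, 0) reference.

    Returns (index of male_a with male_b as rival, index of male_b with
    male_a as rival).  Neither male is pre-selected as "near"; per frame
    at most one of the two indicators can be 1 (a triangle has at most
    one non-acute angle).
    """
    a, b = triad.male_a.fish_id, triad.male_b.fish_id
    return (
        focal_guarding_index(triad, a, reference_id=b),
        focal_guarding_index(triad, b, reference_id=a),
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group a over group b; ties count 1/2."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    Enumerates all C(n_a + n_b, n_a) assignments of the pooled observed
    values to group a, computing the permutation distribution of U (ties
    contribute 1/2, so tied data are handled exactly).  The reported U is
    min(U_a, U_b); the two-sided p-value is the doubled smaller tail,
    capped at 1.  Feasible for group sizes up to ~10; the standard
    dominance protocol uses n = 6 per side (924 assignments).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    u_obs = _u_statistic(a, b)
    n = n_a + n_b
    total = math.comb(n, n_a)
    count_le = 0
    count_ge = 0
    for idx in combinations(range(n), n_a):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if u <= u_obs + 1e-12:
            count_le += 1
        if u >= u_obs - 1e-12:
            count_ge += 1
    p_one = min(count_le, count_ge) / total
    p_two = min(1.0, 2.0 * p_one)
    u_report = min(u_obs, n_a * n_b - u_obs)
    return u_report, p_two


def dominance_test(
    indices_a: Sequence[float] | Sequence[GuardingResult],
    indices_b: Sequence[float] | Sequence[GuardingResult],
    male_a_id: str = "A",
    male_b_id: str = "B",
    alpha: float = 0.05,
) -> DominanceOutcome:
    """Classify a male pair as dominant/subordinate/equal from repeated trials.

    Exact two-sided Mann-Whitney U (full enumeration) for group sizes up
    to 8 per side; a normal approximation with tie correction beyond
    that.  Verdict: ``equal`` if p > alpha, otherwise the male with the
    higher mean index is dominant.
    """

    def _vals(xs) -> tuple[float, ...]:
        return tuple(
            x.guarding_index if isinstance(x, GuardingResult) else float(x) for x in xs
        )

    va, vb = _vals(indices_a), _vals(indices_b)
    if len(va) != len(vb):
        raise PairingError(
            f"index series lengths differ: {len(va)} vs {len(vb)}"
        )
    if len(va) < 2:
        raise PairingError("need >=2 trials per male")
    if max(len(va), len(vb)) <= EXACT_ENUMERATION_MAX_N:
        u, p = mann_whitney_exact(va, vb)
    else:
        res = stats.mannwhitneyu(va, vb, alternative="two-sided", method="asymptotic")
        u = float(min(res.statistic, len(va) * len(vb) - res.statistic))
        p = float(res.pvalue)
    if p > alpha:
        verdict = "equal"
    elif float(np.mean(va)) >= float(np.mean(vb)):
        verdict = "a_dominant"
    else:
        verdict = "b_dominant"
    return DominanceOutcome(
        male_a_id=male_a_id,
        male_b_id=male_b_id,
        indices_a=va,
        indices_b=vb,
        u_statistic=u,
        p_value=p,
        verdict=verdict,
        alpha=alpha,
    )


def proximity_bias_test(triads: Iterable[TriadRecording]) -> ProximityBiasResult:
    """Chi-square test of proximity bias over frames pooled across trials.

    For every complete grid frame, determines which male (by slot:
    male_a vs male_b across trials, i.e. the genotype labels) is closer
    to the female.  Counts are tested against a 50:50 split with a 1-df
    goodness-of-fit chi-square.  Exact-tie frames are excluded from the
    test and reported separately.
    """
    n_a = n_b = n_tie = 0
    id_a = id_b = ""
    for triad in triads:
        id_a, id_b = triad.male_a.fish_id, triad.male_b.fish_id
        mask = triad.complete_frames()
        f = triad.female.positions[mask]
        da = np.linalg.norm(triad.male_a.positions[mask] - f, axis=1)
        db = np.linalg.norm(triad.male_b.positions[mask] - f, axis=1)
        n_a += int(np.sum(da < db))
        n_b += int(np.sum(db < da))
        n_tie += int(np.sum(da == db))
    total = n_a + n_b
    if total == 0:
        raise ValueError("no untied complete frames pooled across trials")
    chi2, p = stats.chisquare([n_a, n_b])
    return ProximityBiasResult(
        male_a_id=id_a,
        male_b_id=id_b,
        n_frames_a_closer=n_a,
        n_frames_b_closer=n_b,
        n_frames_tied=n_tie,
        chi_square=float(chi2),
        p_value=float(p),
    )


def paternity_summary(
    groups: Mapping[str, Sequence[float]],
) -> PaternitySummary:
    """Per-group progeny marker percentages with one-way ANOVA and Scheffé.

    ``groups`` maps a dominance-class label (e.g. "wt_dominant",
    "tg_dominant", "equal") to per-brood percentages of marker-positive
    progeny.  Empty groups are dropped with a warning; >=2 groups with
    >=2 broods each are required.  Scheffé's post-hoc compares every
    label pair: F_pair = (m_i - m_j)^2 / (MSW (1/n_i + 1/n_j)), referred
    to (k-1) F_{k-1, N-k}.
    """
    import warnings

    kept: dict[str, np.ndarray] = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            warnings.warn(f"empty group {label!r} excluded from paternity summary")
            continue
        kept[label] = arr
    if len(kept) < 2 or any(len(v) < 2 for v in kept.values()):
        raise ValueError("need >=2 groups with >=2 broods each")
    labels = tuple(kept)
    arrays = [kept[lb] for lb in labels]
    k = len(arrays)
    n_total = sum(len(x) for x in arrays)
    f_stat, p = stats.f_oneway(*arrays)
    df_b, df_w = k - 1, n_total - k
    msw = sum(np.sum((x - x.mean()) ** 2) for x in arrays) / df_w
    scheffe: dict[tuple[str, str], float] = {}
    for (li, xi), (lj, xj) in combinations(zip(labels, arrays), 2):
        if msw == 0:
            scheffe[(li, lj)] = 1.0 if xi.mean() == xj.mean() else 0.0
            continue
        f_pair = (xi.mean() - xj.mean()) ** 2 / (msw * (1 / len(xi) + 1 / len(xj)))
        scheffe[(li, lj)] = float(stats.f.sf(f_pair / df_b, df_b, df_w))
    sems = tuple(
        float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")
        for x in arrays
    )
    return PaternitySummary(
        group_labels=labels,
        group_means=tuple(float(x.mean()) for x in arrays),
        group_sems=sems,
        group_ns=tuple(len(x) for x in arrays),
        f_statistic=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p_value=float(p),
        scheffe_p=scheffe,
    )
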