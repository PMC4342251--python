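"""Trajectory containers, file I/O, grid resampling, and summary statistics.

The assay samples each fish once every ``step_s`` seconds over a
``window_s``-second trial, endpoints inclusive, giving
``floor(window_s / step_s) + 1`` grid frames (21 for the default
100 s / 5 s protocol).  All downstream geometry operates on tracks that
have been snapped onto this common grid; frames where a fish could not
be located are carried as NaN rows and excluded from denominators, never
interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FishTrack",
    "TriadRecording",
    "SamplingSpec",
    "SchemaError",
    "MalformedTrialError",
    "EmptyOverlapError",
    "UndefinedSpeedError",
    "body_center",
    "read_trajectories",
    "write_trajectories",
    "resample_to_grid",
    "mean_speed",
    "DEFAULT_COLUMNS",
]


class SchemaError(ValueError):
    """A required column is absent or a cell cannot be parsed."""


class MalformedTrialError(ValueError):
    """A trial does not contain exactly one female and two males."""


class EmptyOverlapError(ValueError):
    """A track has no frames inside the requested sampling window."""


class UndefinedSpeedError(ValueError):
    """Fewer than two located frames: speed cannot be computed."""


@dataclass(frozen=True)
class SamplingSpec:
    """Sampling grid for one trial: ``window_s`` seconds at ``step_s`` spacing.

    Grid points are ``0, step, 2*step, ..., window`` inclusive, so the
    default 100 s / 5 s protocol yields 21 frames.  ``alignment_tolerance_s``
    is the maximum offset when snapping a raw frame onto a grid point;
    raw frames further away leave the grid point flagged missing.
    """

    window_s: float = 100.0
    step_s: float = 5.0
    alignment_tolerance_s: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.step_s <= 0:
            raise ValueError("window_s and step_s must be positive")
        if self.alignment_tolerance_s < 0:
            raise ValueError("alignment_tolerance_s must be non-negative")

    @property
    def n_points(self) -> int:
        return int(math.floor(self.window_s / self.step_s + 1e-9)) + 1

    def grid(self) -> np.ndarray:
        return np.arange(self.n_points, dtype=float) * self.step_s


@dataclass
class FishTrack:
    """One fish's identified, time-stamped 2-D positions.

    ``positions`` is an (n, 2) float array aligned with ``timestamps``;
    a missing frame is a NaN row.  Timestamps are strictly increasing.
    """

    fish_id: str
    sex: str  # "female" | "male"
    timestamps: np.ndarray
    positions: np.ndarray
    genotype: str = ""
    species: str = ""
    source: str = "observed"  # "observed" | "simulated" | "merged"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if len(self.timestamps) != len(self.positions):
            raise ValueError("timestamps and positions must have equal length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.isinf(self.positions)):
            raise ValueError("positions must be finite where present")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def present(self) -> np.ndarray:
        """Boolean mask of frames where the fish was located."""
        return ~np.any(np.isnan(self.positions), axis=1)


@dataclass
class TriadRecording:
    """Aligned tracks of one female and two males for a single trial.

    Real, simulated, and merged (superimposed solo) recordings all use
    this container and are analyzed identically.
    """

    trial_id: str
    female: FishTrack
    male_a: FishTrack
    male_b: FishTrack
    condition: str = ""
    arena: tuple[float, float] | None = None
    sampling: SamplingSpec = field(default_factory=SamplingSpec)

    def __post_init__(self) -> None:
        if self.female.sex != "female":
            raise MalformedTrialError(
                f"trial {self.trial_id!r}: female slot holds a {self.female.sex}"
            )
        for m in (self.male_a, self.male_b):
            if m.sex != "male":
                raise MalformedTrialError(
                    f"trial {self.trial_id!r}: male slot holds a {m.sex}"
                )

    @property
    def tracks(self) -> tuple[FishTrack, FishTrack, FishTrack]:
        return (self.female, self.male_a, self.male_b)

    def male(self, fish_id: str) -> FishTrack:
        for m in (self.male_a, self.male_b):
            if m.fish_id == fish_id:
                return m
        raise KeyError(f"no male {fish_id!r} in trial {self.trial_id!r}")

    def complete_frames(self) -> np.ndarray:
        """Mask of grid frames where all three fish were located."""
        mask = self.female.present()
        for m in (self.male_a, self.male_b):
            mask = mask & m.present()
        return mask

    def resampled(self, spec: SamplingSpec | None = None) -> "TriadRecording":
        spec = spec or self.sampling
        return TriadRecording(
            trial_id=self.trial_id,
            female=resample_to_grid(self.female, spec),
            male_a=resample_to_grid(self.male_a, spec),
            male_b=resample_to_grid(self.male_b, spec),
            condition=self.condition,
            arena=self.arena,
            sampling=spec,
        )


def body_center(head, tail):
    """Midpoint of head and tail positions: the body-position convention.

    Returns a NaN point (missing-frame flag) if either input is missing
    or non-finite, rather than raising.
    """
    head = np.asarray(head, dtype=float)
    tail = np.asarray(tail, dtype=float)
    if not (np.all(np.isfinite(head)) and np.all(np.isfinite(tail))):
        return np.array([np.nan, np.nan])
    return (head + tail) / 2.0


def resample_to_grid(track: FishTrack, spec: SamplingSpec) -> FishTrack:
    """Snap a raw track onto the inclusive sampling grid.

    Each grid point takes the nearest raw frame within
    ``spec.alignment_tolerance_s``; otherwise it is flagged missing.
    Idempotent: resampling an already-gridded track is a no-op.
    """
    grid = spec.grid()
    raw_t = track.timestamps
    present = track.present()
    if raw_t.size == 0 or raw_t[present].size == 0:
        raise EmptyOverlapError(f"track {track.fish_id!r} has no located frames")
    t_ok = raw_t[present]
    if t_ok.max() < grid[0] - spec.alignment_tolerance_s or t_ok.min() > grid[-1] + spec.alignment_tolerance_s:
        raise EmptyOverlapError(
            f"track {track.fish_id!r} lies entirely outside the sampling window"
        )
    pos = np.full((len(grid), 2), np.nan)
    idx_ok = np.flatnonzero(present)
    for gi, gt in enumerate(grid):
        offsets = np.abs(raw_t[idx_ok] - gt)
        j = int(np.argmin(offsets))
        if offsets[j] <= spec.alignment_tolerance_s:
            pos[gi] = track.positions[idx_ok[j]]
    return replace(track, timestamps=grid, positions=pos)


def mean_speed(track: FishTrack, window_s: float | None = None) -> float:
    """Mean speed: total path length over elapsed time between located frames.

    Consecutive located frames define Euclidean step segments; the sum of
    segment lengths is divided by the total elapsed time they span.  When
    ``window_s`` is given, only frames with timestamp <= window_s count.
    """
    mask = track.present()
    if window_s is not None:
        mask = mask & (track.timestamps <= window_s + 1e-9)
    t = track.timestamps[mask]
    p = track.positions[mask]
    if len(t) < 2:
        raise UndefinedSpeedError(
            f"track {track.fish_id!r}: need >=2 located frames, have {len(t)}"
        )
    dist = float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
    elapsed = float(np.sum(np.diff(t)))
    return dist / elapsed


# ---------------------------------------------------------------------------
# Tabular file I/O
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS: dict[str, str] = {
    "trial_id": "trial_id",
    "condition": "condition",
    "fish_id": "fish_id",
    "role": "role",
    "genotype": "genotype",
    "species": "species",
    "time_s": "time_s",
    "x": "x",
    "y": "y",
    "head_x": "head_x",
    "head_y": "head_y",
    "tail_x": "tail_x",
    "tail_y": "tail_y",
}

_REQUIRED = ("trial_id", "fish_id", "role", "time_s")
_OPTIONAL_META = ("condition", "genotype", "species")


def load_column_map(path: str | Path) -> dict[str, str]:
    """Read a YAML/JSON key-value file overriding canonical column names."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping):
        raise SchemaError(f"column map {path} must be a key-value mapping")
    out = dict(DEFAULT_COLUMNS)
    for key, val in mapping.items():
        if key not in DEFAULT_COLUMNS:
            raise SchemaError(f"unknown canonical column {key!r} in map {path}")
        out[key] = str(val)
    return out


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_trajectories(
    path: str | Path,
    schema: Mapping[str, str] | str | Path | None = None,
    sampling: SamplingSpec | None = None,
    resample: bool = True,
    min_retained_fraction: float = 0.8,
) -> list[TriadRecording]:
    """Read a delimited trajectory table into one TriadRecording per trial.

    The table has one row per fish per frame with columns ``trial_id``,
    ``fish_id``, ``role`` (female|male), ``time_s``, and either ``x, y``
    or ``head_x, head_y, tail_x, tail_y`` (collapsed to body centers).
    Empty coordinate cells mark missing frames.  ``schema`` may be a
    column mapping or a path to a YAML/JSON mapping file.

    Trials retaining fewer than ``min_retained_fraction`` of complete grid
    frames after resampling are rejected (set to 0 to disable).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(schema, (str, Path)):
        cols = load_column_map(schema)
    else:
        cols = dict(DEFAULT_COLUMNS)
        if schema:
            cols.update(schema)

    df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    for key in _REQUIRED:
        if cols[key] not in df.columns:
            raise SchemaError(f"missing required column {cols[key]!r} in {path}")
    has_xy = cols["x"] in df.columns and cols["y"] in df.columns
    has_ht = all(cols[k] in df.columns for k in ("head_x", "head_y", "tail_x", "tail_y"))
    if not (has_xy or has_ht):
        raise SchemaError(
            f"{path}: need either ({cols['x']}, {cols['y']}) or head/tail coordinate columns"
        )

    def _num(series: pd.Series, colname: str) -> np.ndarray:
        vals = np.empty(len(series), dtype=float)
        for i, (row_idx, raw) in enumerate(series.items()):
            s = str(raw).strip()
            if s == "":
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(s)
            except ValueError:
                raise SchemaError(
                    f"{path}: non-numeric value {raw!r} in column {colname!r}, file row {row_idx + 2}"
                ) from None
        return vals

    spec = sampling or SamplingSpec()
    recordings: list[TriadRecording] = []
    for trial_id, trial_df in df.groupby(cols["trial_id"], sort=True):
        tracks: list[FishTrack] = []
        condition = ""
        for fish_id, fish_df in trial_df.groupby(cols["fish_id"], sort=True):
            fish_df = fish_df.sort_values(cols["time_s"], key=lambda s: s.astype(float))
            t = _num(fish_df[cols["time_s"]], cols["time_s"])
            if has_xy:
                xy = np.column_stack(
                    [_num(fish_df[cols["x"]], cols["x"]), _num(fish_df[cols["y"]], cols["y"])]
                )
            else:
                heads = np.column_stack(
                    [_num(fish_df[cols["head_x"]], cols["head_x"]),
                     _num(fish_df[cols["head_y"]], cols["head_y"])]
                )
                tails = np.column_stack(
                    [_num(fish_df[cols["tail_x"]], cols["tail_x"]),
                     _num(fish_df[cols["tail_y"]], cols["tail_y"])]
                )
                xy = np.array([body_center(h, tl) for h, tl in zip(heads, tails)])
            role = str(fish_df[cols["role"]].iloc[0]).strip().lower()
            if role not in ("female", "male"):
                raise MalformedTrialError(
                    f"trial {trial_id!r}: fish {fish_id!r} has role {role!r}"
                )
            meta = {}
            for key in _OPTIONAL_META:
                if cols[key] in fish_df.columns:
                    meta[key] = str(fish_df[cols[key]].iloc[0])
            condition = meta.get("condition", condition)
            tracks.append(
                FishTrack(
                    fish_id=str(fish_id),
                    sex=role,
                    timestamps=t,
                    positions=xy,
                    genotype=meta.get("genotype", ""),
                    species=meta.get("species", ""),
                )
            )
        females = [tr for tr in tracks if tr.sex == "female"]
        males = [tr for tr in tracks if tr.sex == "male"]
        if len(tracks) != 3 or len(females) != 1 or len(males) != 2:
            raise MalformedTrialError(
                f"trial {trial_id!r}: expected 1 female + 2 males, "
                f"got {len(females)} female(s) and {len(males)} male(s)"
            )
        rec = TriadRecording(
            trial_id=str(trial_id),
            female=females[0],
            male_a=males[0],
            male_b=males[1],
            condition=condition,
            sampling=spec,
        )
        if resample:
            rec = rec.resampled(spec)
            retained = rec.complete_frames().mean()
            if retained < min_retained_fraction:
                raise MalformedTrialError(
                    f"trial {trial_id!r}: only {retained:.0%} of grid frames complete "
                    f"(minimum {min_retained_fraction:.0%})"
                )
        recordings.append(rec)
    return recordings


def write_trajectories(
    recordings: Iterable[TriadRecording], path: str | Path, sep: str = "\t"
) -> None:
    """Write recordings in the canonical trajectory-table format."""
    rows = []
    for rec in recordings:
        for track in rec.tracks:
            for t, (x, y) in zip(track.timestamps, track.positions):
                rows.append(
                    {
                        "trial_id": rec.trial_id,
                        "condition": rec.condition,
                        "fish_id": track.fish_id,
                        "role": track.sex,
                        "genotype": track.genotype,
                        "species": track.species,
                        "time_s": f"{t:g}",
                        "x": "" if np.isnan(x) else f"{x:.6f}",
                        "y": "" if np.isnan(y) else f"{y:.6f}",
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
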