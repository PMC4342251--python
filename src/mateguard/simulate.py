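"""Seeded simulator of triad and solo swimming trajectories.

The movement model is a bounded correlated random walk with weighted
steering.  Each fish carries a heading that persists between internal
time steps; males in interacting mode additionally steer toward the
female (attraction) and toward an interposition point on the segment
from the female toward the rival (guarding drive).  The guarding drive
is the single knob that moves a male from indifferent swimming to
strong mate-guarding; with it at zero, or in independent mode, each
fish performs a plain correlated random walk, which is the statistical
structure the merged-control null assumes.

Trajectories evolve at a fine internal step (0.5 s by default) inside a
reflecting rectangular arena matching the assay tank footprint
(19 cm x 13 cm) and are sub-sampled onto the standard 5-s / 100-s
observation grid.  Identical configuration + seed reproduces identical
output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .trajectories import (
    FishTrack,
    SamplingSpec,
    TriadRecording,
    write_trajectories,
)
from .guarding import build_merged_control

__all__ = [
    "SimulationConfig",
    "simulate_triad",
    "simulate_solo_set",
    "simulate_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the triad movement model.

    arena : (width, height) in cm; the assay tank footprint by default.
    duration_s, dt_s : simulated span and internal step; dt_s must divide
        the observation grid step.
    female_speed, male_speed : swimming speeds in cm/s.
    guard_drive_a, guard_drive_b : dimensionless steering weights toward
        the interposition point for each male; 0 = no guarding.
    attract_weight : steering weight toward the female.
    interpose_fraction : position of the interposition target along the
        female-to-rival segment (0 = on the female, 1 = on the rival).
    persistence : weight of the previous heading (directional inertia of
        the correlated random walk).
    noise_sd : scale of the isotropic Gaussian steering noise.
    mode : "interacting" couples the males to the female and rival;
        "independent" zeroes all coupling so the three fish swim as if
        in separate aquaria.
    """

    arena: tuple[float, float] = (19.0, 13.0)
    duration_s: float = 100.0
    dt_s: float = 0.5
    female_speed: float = 3.0
    male_speed: float = 3.0
    guard_drive_a: float = 3.0
    guard_drive_b: float = 3.0
    attract_weight: float = 1.0
    interpose_fraction: float = 0.25
    persistence: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0
    mode: str = "interacting"
    sampling: SamplingSpec = field(default_factory=SamplingSpec)

    def __post_init__(self) -> None:
        if self.arena[0] <= 0 or self.arena[1] <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.duration_s <= 0 or self.dt_s <= 0:
            raise ValueError("duration_s and dt_s must be positive")
        if self.mode not in ("interacting", "independent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        steps_per_grid = self.sampling.step_s / self.dt_s
        if abs(steps_per_grid - round(steps_per_grid)) > 1e-9:
            raise ValueError("dt_s must divide the sampling grid step")
        for w in (
            self.guard_drive_a,
            self.guard_drive_b,
            self.attract_weight,
            self.persistence,
            self.noise_sd,
        ):
            if w < 0:
                raise ValueError("steering weights must be non-negative")


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 1e-12 else np.zeros_like(v)


def _reflect(p: np.ndarray, h: np.ndarray, arena: tuple[float, float]) -> None:
    """Reflect position and heading at the arena walls, in place."""
    for axis, limit in enumerate(arena):
        # Repeated folding handles steps longer than the arena.
        while p[axis] < 0 or p[axis] > limit:
            if p[axis] < 0:
                p[axis] = -p[axis]
            else:
                p[axis] = 2 * limit - p[axis]
            h[axis] = -h[axis]


def _simulate_paths(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Run the internal-step dynamics; returns (times, positions[3, n, 2]).

    Fish order: female, male a, male b.
    """
    n_steps = int(round(config.duration_s / config.dt_s))
    times = np.arange(n_steps + 1) * config.dt_s
    arena = config.arena
    pos = np.empty((3, n_steps + 1, 2))
    p = rng.uniform([0.0, 0.0], arena, size=(3, 2))
    theta = rng.uniform(0, 2 * np.pi, size=3)
    h = np.column_stack([np.cos(theta), np.sin(theta)])
    pos[:, 0] = p
    speeds = np.array([config.female_speed, config.male_speed, config.male_speed])
    drives = np.array([0.0, config.guard_drive_a, config.guard_drive_b])
    interacting = config.mode == "interacting"
    attract = config.attract_weight if interacting else 0.0
    g = config.interpose_fraction
    for step in range(1, n_steps + 1):
        noise = rng.normal(scale=config.noise_sd, size=(3, 2))
        female_xy = p[0].copy()
        for i in range(3):
            d = config.persistence * h[i] + noise[i]
            if i > 0 and interacting:
                rival_xy = p[3 - i]  # the other male
                target = female_xy + g * (rival_xy - female_xy)
                d = d + attract * _unit(female_xy - p[i])
                d = d + drives[i] * _unit(target - p[i])
            d = _unit(d)
            if not d.any():  # fully cancelled steering: keep heading
                d = h[i]
            h[i] = d
            p[i] = p[i] + speeds[i] * config.dt_s * h[i]
            _reflect(p[i], h[i], arena)
        pos[:, step] = p
    return times, pos


def _to_grid(times: np.ndarray, xy: np.ndarray, spec: SamplingSpec) -> tuple[np.ndarray, np.ndarray]:
    grid = spec.grid()
    idx = np.array([int(round(t / (times[1] - times[0]))) for t in grid])
    return grid, xy[idx]


def simulate_triad(config: SimulationConfig, trial_id: str = "sim") -> TriadRecording:
    """Simulate one triad trial and sub-sample it onto the observation grid.

    In ``independent`` mode each fish is simulated in its own virtual
    arena with its own random stream, so their paths share no
    dependence whatsoever.
    """
    spec = config.sampling
    if config.mode == "independent":
        tracks_xy = []
        times = None
        for i in range(3):
            sub = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence([config.seed, i])
            ))
            solo = replace(config, mode="interacting", guard_drive_a=0.0,
                           guard_drive_b=0.0, attract_weight=0.0)
            times, pos = _simulate_paths(solo, sub)
            tracks_xy.append(pos[i])
        pos = np.stack(tracks_xy)
        source = "merged"
    else:
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed])))
        times, pos = _simulate_paths(config, rng)
        source = "simulated"
    grid, _ = _to_grid(times, pos[0], spec)
    roles = [("F", "female"), ("Ma", "male"), ("Mb", "male")]
    tracks = []
    for i, (fid, sex) in enumerate(roles):
        _, xy = _to_grid(times, pos[i], spec)
        tracks.append(
            FishTrack(
                fish_id=f"{trial_id}_{fid}",
                sex=sex,
                timestamps=grid,
                positions=xy,
                source=source,
            )
        )
    return TriadRecording(
        trial_id=trial_id,
        female=tracks[0],
        male_a=tracks[1],
        male_b=tracks[2],
        condition="merge" if config.mode == "independent" else "interacting",
        arena=config.arena,
        sampling=spec,
    )


def simulate_solo_set(
    config: SimulationConfig, n_trials: int
) -> list[tuple[FishTrack, FishTrack, FishTrack]]:
    """Simulate ``n_trials`` independent (female, male, male) solo triples.

    Suitable for :func:`mateguard.guarding.build_merged_control`; per-trial
    seeds derive deterministically from the base seed (base + trial index).
    """
    triples = []
    for k in range(n_trials):
        cfg = replace(config, mode="independent", seed=config.seed + k)
        rec = simulate_triad(cfg, trial_id=f"solo{k:02d}")
        triples.append((rec.female, rec.male_a, rec.male_b))
    return triples


def simulate_experiment(
    config: SimulationConfig,
    n_trials: int,
    design: str,
    out_path: str | Path,
    merged_config: SimulationConfig | None = None,
) -> list[TriadRecording]:
    """Write a complete synthetic study in the trajectory-table format.

    ``design="guarding_test"`` produces ``n_trials`` interacting triads
    plus ``n_trials`` merged controls (independent fish superimposed);
    ``design="dominance_test"`` produces ``n_trials`` repeated sessions
    (6 in the standard protocol) of the same simulated male pair.
    Returns the recordings in file order.
    """
    recordings: list[TriadRecording] = []
    if design == "guarding_test":
        for k in range(n_trials):
            cfg = replace(config, mode="interacting", seed=config.seed + k)
            recordings.append(simulate_triad(cfg, trial_id=f"exp{k:02d}"))
        mcfg = merged_config or config
        for k, (f, m1, m2) in enumerate(
            simulate_solo_set(replace(mcfg, seed=mcfg.seed + 1000), n_trials)
        ):
            recordings.append(
                build_merged_control(f, m1, m2, trial_id=f"mrg{k:02d}")
            )
    elif design == "dominance_test":
        for k in range(n_trials):
            cfg = replace(config, mode="interacting", seed=config.seed + k)
            recordings.append(simulate_triad(cfg, trial_id=f"ses{k:02d}"))
    else:
        raise ValueError(f"unknown design {design!r}")
    write_trajectories(recordings, out_path)
    return recordings
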