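import numpy as np
import pytest

from mateguard import FishTrack, SamplingSpec, TriadRecording

GRID = SamplingSpec().grid()  # 0..100 s by 5 s, 21 points


def make_track(fish_id, sex, positions, timestamps=None, **kw):
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:  # a single static position, tiled over the grid
        positions = np.tile(positions, (len(GRID), 1))
    if timestamps is None:
        timestamps = GRID[: len(positions)]
    return FishTrack(fish_id=fish_id, sex=sex, timestamps=timestamps,
                     positions=positions, **kw)


def make_triad(female_xy, male_a_xy, male_b_xy, trial_id="T1", **kw):
    """Triad from static points or (n, 2) paths on the default grid."""
    return TriadRecording(
        trial_id=trial_id,
        female=make_track("F", "female", female_xy),
        male_a=make_track("A", "male", male_a_xy),
        male_b=make_track("B", "male", male_b_xy),
        **kw,
    )


def random_triad(rng, n_frames=21, scale=10.0, trial_id="R1"):
    paths = rng.uniform(0, scale, size=(3, n_frames, 2))
    return make_triad(*paths, trial_id=trial_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def tmp_table(tmp_path):
    """Write rows (list of dicts) as a CSV trajectory table; returns the path."""

    def _write(rows, name="traj.csv"):
        import pandas as pd

        path = tmp_path / name
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    return _write
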