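import numpy as np
import pytest

from lymphwalk.trackio import Field, Track


def make_track(xyz, dt=15.0, track_id="t0", t0=0.0):
    """Track from a position array at a regular frame interval."""
    xyz = np.asarray(xyz, dtype=float)
    t = t0 + np.arange(len(xyz)) * dt
    return Track(track_id, t, xyz, dt)


def straight_track(n=10, speed=0.2, dt=15.0, direction=(1.0, 0.0, 0.0),
                   start=(0.0, 0.0, 0.0), track_id="straight"):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    xyz = np.asarray(start, float) + np.outer(np.arange(n) * speed * dt, d)
    return make_track(xyz, dt, track_id)


def field_of(tracks, box=None, dt=None):
    pts = np.vstack([tr.xyz for tr in tracks])
    bbox = (np.array([pts.min(0), pts.max(0)]) if box is None
            else np.asarray(box, float))
    return Field("test", list(tracks),
                 bbox, dt if dt is not None else tracks[0].frame_dt)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def logmcrw_field():
    """A moderately sized synthetic field shared across tests (read-only)."""
    from lymphwalk.synthetic_data import GeneratorSpec, gen_field

    fld, truth = gen_field(GeneratorSpec(model="logmcrw", n_tracks=150, seed=7))
    return fld


@pytest.fixture(scope="session")
def filtered_field(logmcrw_field):
    from lymphwalk.trackio import filter_motile

    return filter_motile(logmcrw_field)


@pytest.fixture(scope="session")
def walker_params(filtered_field):
    from lymphwalk.simulator import fit_walker_params

    return fit_walker_params(filtered_field)
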