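import numpy as np
import pytest

from gaitpipe import SimulationConfig, generate_session
from gaitpipe.io import SEGMENTS, MarkerlessRecording, PersonTrack, PoseSeries, WalkwayFrame
from gaitpipe.report import analyze_session


@pytest.fixture(scope="session")
def base_config():
    return SimulationConfig(n_passes=2, seed=11)


@pytest.fixture(scope="session")
def session(base_config):
    return generate_session(base_config)


@pytest.fixture(scope="session")
def analysis(session):
    return analyze_session(session.mlmc, session.psw)


def make_track(pelvis_xyz, valid=None, rate=60.0, person_id="p0"):
    """Minimal 7-segment track: identity rotations, all segments sharing the
    pelvis translation (sufficient for pass/selection logic)."""
    pelvis_xyz = np.asarray(pelvis_xyz, dtype=float)
    n = pelvis_xyz.shape[0]
    if valid is None:
        valid = np.ones(n, dtype=bool)
    t = np.tile(np.eye(4), (n, 1, 1))
    t[:, :3, 3] = pelvis_xyz
    poses = {seg: PoseSeries(t.copy(), np.asarray(valid, bool).copy())
             for seg in SEGMENTS}
    return PersonTrack(person_id, rate, poses)


def make_recording(tracks, rate=60.0, walkway=None, pass_id=0):
    return MarkerlessRecording(
        session_id="test", pass_id=pass_id, rate=rate, tracks=tracks,
        walkway=walkway or WalkwayFrame(),
    )
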