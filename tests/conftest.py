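import numpy as np
import pytest
from hypothesis import settings

import mothfan as mf
from mothfan.synthetic import AnalyticFlowSpec

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_spec():
    """Typical fanning kinematics (the generator defaults)."""
    return mf.KinematicsSpec()


@pytest.fixture(scope="session")
def clean_track(default_spec):
    """Noise-free landmark track from the default kinematics."""
    return mf.generate_landmarks(default_spec, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def recon_kin(clean_track):
    """Kinematics reconstructed from the noise-free track."""
    return mf.reconstruct(clean_track)


@pytest.fixture(scope="session")
def stereo_cameras():
    """Two synchronised cameras looking at the working volume."""
    target = (0.01, 0.0, 0.02)
    return [
        mf.CameraModel.looking_at((0.45, -0.25, 0.25), target),
        mf.CameraModel.looking_at((0.05, 0.5, 0.3), target),
    ]


@pytest.fixture(scope="session")
def small_flow_spec():
    """Compact flow domain that still contains the moth and antenna."""
    return AnalyticFlowSpec(
        kind="flapping_dipole",
        domain_lo=(-0.06, -0.05, 0.0),
        domain_hi=(0.08, 0.05, 0.08),
        spacing=5e-3,
        frequency=48.9,
    )


@pytest.fixture(scope="session")
def induced_field(recon_kin, small_flow_spec):
    return mf.generate_induced_flow(recon_kin, small_flow_spec)


@pytest.fixture(scope="session")
def left_antenna(clean_track):
    base = clean_track.landmark("antenna_base", "L").mean(axis=0)
    tip = clean_track.landmark("antenna_tip", "L").mean(axis=0)
    return mf.VirtualAntenna(base, tip, 21)


@pytest.fixture(scope="session")
def head_heading(clean_track):
    head = clean_track.landmark("head_tip", "C").mean(axis=0)
    abdomen = clean_track.landmark("abdomen_tip", "C").mean(axis=0)
    heading = head - abdomen
    return head, heading / np.linalg.norm(heading)
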