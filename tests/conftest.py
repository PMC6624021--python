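import numpy as np
import pytest

from condmotion import compo, detect, synthio, trackmotion
from condmotion import synapse as synapse_mod


@pytest.fixture(scope="session")
def step_g():
    return lambda r: 1.0 if r > 0.6 else 0.5


@pytest.fixture(scope="session")
def synapse_movie(step_g):
    """One synapse movie with a step decay ground truth, plus geometry."""
    master, slave, truth = synthio.make_synapse_movie(
        60, 60.0, 12.0, 25, decay_g=step_g, noise_sd=4.0, seed=12)
    geom = synapse_mod.segment_geometry(master)
    return master, slave, truth, geom


@pytest.fixture(scope="session")
def synapse_pipeline(synapse_movie):
    """Detection, tracks and per-channel contents for the step movie."""
    master, slave, truth, geom = synapse_movie
    dets = detect.detect_stack_maxima(master, psf_sigma_px=1.2)
    tracks = trackmotion.link_tracks(dets)
    m_cont = compo.track_contents(master, dets, tracks, geom=geom)
    s_cont = compo.track_contents(slave, dets, tracks, geom=geom)
    return dets, tracks, m_cont, s_cont


@pytest.fixture(scope="session")
def circle_geometry():
    """A clean circular synapse with centered cSMAC for geometry math."""
    master, _, truth = synthio.make_synapse_movie(
        3, 60.0, 12.0, 0, noise_sd=1.0, seed=3)
    geom = synapse_mod.segment_geometry(master)
    return geom, truth
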