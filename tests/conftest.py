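import numpy as np
import pytest

from lipdyn.trajectory_model import FrameSeries, ParticleMeta


@pytest.fixture
def small_meta() -> ParticleMeta:
    """3-residue protein (one bead each) plus two single-bead GM3 lipids."""
    return ParticleMeta(
        residue_ids=np.array([1, 2, 3, 1, 2]),
        residue_names=np.array(["ALA", "GLY", "LYS", "GM3", "GM3"]),
        segment_ids=np.array(["PROT", "PROT", "PROT", "MEMB", "MEMB"]),
        particle_names=np.array(["BB", "BB", "BB", "HG", "HG"]),
        categories=np.array(["protein", "protein", "protein", "lipid", "lipid"]),
        species=np.array(["", "", "", "GM3", "GM3"]),
    )


@pytest.fixture
def single_frame(small_meta) -> FrameSeries:
    coords = np.array([[
        [1.0, 1.0, 1.0],
        [2.0, 1.0, 1.0],
        [3.0, 1.0, 1.0],
        [5.0, 5.0, 1.0],
        [8.0, 8.0, 1.0],
    ]])
    return FrameSeries(
        times=np.array([0.0]),
        coordinates=coords,
        box=np.array([[10.0, 10.0, 10.0]]),
    )


def brute_force_min_image_distance(a, b, box, n_images=3):
    """Minimum distance between two points over a periodic image grid.

    ``n_images=1`` is the classic 27-image search; a wider grid covers
    unwrapped inputs lying several box lengths apart.
    """
    rng = range(-n_images, n_images + 1)
    best = np.inf
    for ix in rng:
        for iy in rng:
            for iz in rng:
                shift = np.array([ix, iy, iz]) * box
                best = min(best, float(np.linalg.norm(a - (b + shift))))
    return best


def brute_force_contact_states(distances, d_on, d_off):
    """Direct per-frame re-simulation of the dual-cutoff automaton."""
    bound = False
    states = []
    for d in distances:
        if not bound and d < d_on:
            bound = True
        elif bound and d > d_off:
            bound = False
        states.append(bound)
    return np.array(states, dtype=bool)
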