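import numpy as np
import pytest

from astromorph.phantoms import PhantomSpec, make_star_astrocyte
from astromorph.segmentation import segment_cell, separate_soma
from astromorph.sholl import skeletonize_processes, sholl_profile


@pytest.fixture
def star_spec():
    """Canonical star: soma radius 10, 4 axis-aligned unbranched arms of 60 px."""
    return PhantomSpec(soma_radius=10, n_primaries=4, arm_length=60, binary=True)


@pytest.fixture
def star_cell(star_spec):
    image, truth = make_star_astrocyte(star_spec)
    return image, truth


@pytest.fixture
def star_analysis(star_cell):
    """Full single-cell analysis of the canonical star phantom."""
    image, truth = star_cell
    cell = segment_cell(image, threshold_mode=0.5)
    seg = separate_soma(cell)
    skel = skeletonize_processes(seg.process_mask, seg.soma_mask)
    profile = sholl_profile(skel, seg.soma_center, interval=10, mode="run")
    return image, truth, seg, skel, profile


def analyze_phantom(image, mode="run", interval=10):
    """Segment -> soma split -> skeleton -> profile, for test reuse."""
    cell = segment_cell(image, threshold_mode=0.5)
    seg = separate_soma(cell)
    skel = skeletonize_processes(seg.process_mask, seg.soma_mask)
    profile = sholl_profile(skel, seg.soma_center, interval=interval, mode=mode)
    return seg, skel, profile


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
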