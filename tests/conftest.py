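import numpy as np
import pytest

import fgfield as fg
from fgfield.crf_estimation import CRF


@pytest.fixture(scope="session")
def crf_left():
    """An isotropic CRF centered 4 cells left of the patch center."""
    return CRF(center=(12.0, 8.0), sd_major=3.0, sd_minor=3.0, orientation=0.0,
               amplitude=20.0, baseline=1.0)


@pytest.fixture(scope="session")
def halfplane_set():
    """48 half-plane labels (24 orientations, both polarities) on 25x25."""
    return fg.gen_halfplane_labels(24, 25)


@pytest.fixture(scope="session")
def halfplane_dense():
    """210 half-plane labels (105 orientations), the full-scale ensemble size."""
    return fg.gen_halfplane_labels(105, 25)


@pytest.fixture(scope="session")
def curved_set():
    """60 curved-boundary labels with moderate curvature."""
    return fg.gen_curved_labels(30, 25, curvature_sd=1.5, seed=11)


@pytest.fixture(scope="session")
def dot_set_9():
    """Exhaustive +/-1 dot set on a 9x9 grid (162 stimuli)."""
    return fg.gen_dot_stimuli(9)


@pytest.fixture(scope="session")
def ideal_kernel(halfplane_dense, crf_left):
    """Ideal figure-preferring kernel on the dense half-plane ensemble."""
    return fg.ideal_rffg(halfplane_dense, crf_left, "figure")


@pytest.fixture(scope="session")
def energy_setup(halfplane_dense, crf_left):
    """An energy cell whose kernel lies in the label span, with its STA/STC.

    The kernel is the unit-norm ideal antagonistic kernel; the cell's rate
    is |<k, label>| so the spike-weighted mean vanishes on the swap-closed
    ensemble while the covariance difference exposes k.
    """
    ideal = fg.ideal_rffg(halfplane_dense, crf_left, "figure")
    k = ideal.grid / np.linalg.norm(ideal.grid)
    neuron = fg.VirtualNeuron(kind="energy", kernel=k, gain=30.0, noise="exact")
    spikes = fg.simulate_responses(neuron, halfplane_dense, n_trials=1, seed=0)
    sta = fg.compute_sta(halfplane_dense, spikes)
    weights = fg.normalize_spikes(spikes, order=halfplane_dense.ids)
    stc_res = fg.compute_stc(halfplane_dense, weights, sta)
    return {"kernel": k, "spikes": spikes, "sta": sta, "stc": stc_res,
            "labels": halfplane_dense}
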