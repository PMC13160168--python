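import numpy as np
import pytest

from shiftmatch.model import ModelParams, solve_omega
from shiftmatch.peaklist import Peak, PeakList


@pytest.fixture
def simple_params() -> ModelParams:
    """A small, hand-checkable parameter set (omega tied at Dmax)."""
    p = ModelParams(
        frechet_shape=1.5,
        frechet_scale=8.0,
        mixture_weight=0.2,
        nomatch_level=1.0,
        prior_a=1.0,
        prior_b=4.0,
        max_csp_distance=400.0,
        dof=2,
    )
    return p.with_(nomatch_level=solve_omega(p))


def make_peaklist(shifts, sigmas=(0.0015, 0.015), nuclei=("H", "N"), spectrum_id="test"):
    return PeakList(
        spectrum_id=spectrum_id,
        sigmas=tuple(sigmas),
        peaks=[Peak(peak_id=i, shifts=tuple(s), label=f"P{i}") for i, s in enumerate(shifts)],
        axis_nuclei=tuple(nuclei),
    )


@pytest.fixture
def peaklist_factory():
    return make_peaklist


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
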