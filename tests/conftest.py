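import numpy as np
import pytest

from thetagate.network import NetworkSpec


@pytest.fixture
def single_stellate():
    """One isolated stellate cell at the default constant drive."""
    return NetworkSpec(
        n_stellate=1, n_interneuron=0,
        w_ie=np.zeros((0, 1)), w_ei=np.zeros((1, 0)), w_ii=np.zeros((0, 0)),
        iext_s=np.array([-2.7]), iext_i=np.zeros(0), name="single_stellate",
    )


@pytest.fixture
def single_interneuron():
    """One isolated interneuron at the default constant drive."""
    return NetworkSpec(
        n_stellate=0, n_interneuron=1,
        w_ie=np.zeros((1, 0)), w_ei=np.zeros((0, 1)), w_ii=np.zeros((1, 1)),
        iext_s=np.zeros(0), iext_i=np.array([0.2]), name="single_interneuron",
    )


def make_single_stellate(i_ext: float) -> NetworkSpec:
    return NetworkSpec(
        n_stellate=1, n_interneuron=0,
        w_ie=np.zeros((0, 1)), w_ei=np.zeros((1, 0)), w_ii=np.zeros((0, 0)),
        iext_s=np.array([i_ext]), iext_i=np.zeros(0),
    )


def make_single_interneuron(i_ext: float) -> NetworkSpec:
    return NetworkSpec(
        n_stellate=0, n_interneuron=1,
        w_ie=np.zeros((1, 0)), w_ei=np.zeros((0, 1)), w_ii=np.zeros((1, 1)),
        iext_s=np.zeros(0), iext_i=np.array([i_ext]),
    )
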