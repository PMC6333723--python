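import numpy as np
import pytest

from gmedge.phantom import PhantomSpec, build_label_map, render_early, render_late


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(noise_scale=0.0)


@pytest.fixture(scope="session")
def default_labels(default_spec):
    return build_label_map(default_spec)


@pytest.fixture(scope="session")
def default_early(default_labels, default_spec):
    return render_early(default_labels, default_spec)


@pytest.fixture(scope="session")
def default_late(default_labels, default_spec):
    return render_late(default_labels, default_spec)


@pytest.fixture(scope="session")
def small_spec():
    # coarse grid keeps registration tests fast; anatomy is unchanged
    return PhantomSpec(shape=(48, 48, 40), spacing=(4.0, 4.0, 4.0), noise_scale=0.0)


@pytest.fixture(scope="session")
def small_early(small_spec):
    labels = build_label_map(small_spec)
    return render_early(labels, small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
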