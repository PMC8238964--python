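"""Shared fixtures: one small synthetic network and its renders.

The small 1.5015 mm field (231 px at 6.5 um) keeps unit tests fast;
field sizes must be integer multiples of the 6.5 um pixel pitch.
Session scope is safe because all fixtures are treated as read-only.
"""

import warnings

import pytest

from rhocta import ArtifactParams, add_artifacts, generate_network, render_enface

warnings.filterwarnings("ignore", category=UserWarning, module="skimage")

SMALL_FIELD_MM = 1.5015
SEED = 1


@pytest.fixture(scope="session")
def small_network():
    return generate_network(
        field_size_mm=SMALL_FIELD_MM, target_density=0.25, seed=SEED
    )


@pytest.fixture(scope="session")
def baseline_render(small_network):
    return render_enface(small_network, "baseline")


@pytest.fixture(scope="session")
def hyperemia_render(small_network):
    return render_enface(small_network, "hyperemia")


@pytest.fixture(scope="session")
def compressed_render(small_network):
    return render_enface(small_network, "compressed")


@pytest.fixture(scope="session")
def noisy_baseline(baseline_render):
    image, _ = baseline_render
    return add_artifacts(image, ArtifactParams(seed=SEED + 100))
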