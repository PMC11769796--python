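import numpy as np
import pytest

from domescope import phantom


@pytest.fixture(scope="session")
def two_dome_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(
        width=256,
        height=256,
        n_sections=16,
        noise_sd=0.02,
        domes=[
            phantom.Dome(cx=80, cy=80, radius=40, cap_height_um=10),
            phantom.Dome(cx=180, cy=180, radius=40, cap_height_um=10),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def two_dome_phantom(two_dome_spec):
    return phantom.generate_phantom(two_dome_spec)


@pytest.fixture(scope="session")
def flat_spec() -> phantom.PhantomSpec:
    return phantom.PhantomSpec(
        width=128, height=128, n_sections=10, noise_sd=0.0, base_coverage=1.0, seed=5
    )


def aggregate_iou(masks, truth_masks) -> float:
    num = den = 0
    for m, t in zip(masks, truth_masks):
        num += np.logical_and(m.data, t).sum()
        den += np.logical_or(m.data, t).sum()
    return num / den
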