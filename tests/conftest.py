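"""Shared fixtures: trained backends (once per session) and stock phantoms."""

import numpy as np
import pytest

from fundustriage.synthetic import ArtefactKind, default_spec, generate_fundus
from fundustriage.training import train_default_backends


@pytest.fixture(scope="session")
def backends():
    """The four default backends trained once from seed 1."""
    return train_default_backends(seed=1)


@pytest.fixture(scope="session")
def clean_phantom():
    """An artefact-free left-eye phantom (image, ground truth)."""
    return generate_fundus(default_spec(seed=500))


@pytest.fixture(scope="session")
def eyelash_phantom():
    """A phantom with ~40% eyelash coverage (image, ground truth)."""
    return generate_fundus(default_spec(
        seed=501, artefact_kind=ArtefactKind.EYELASH,
        artefact_coverage_target=0.4))


@pytest.fixture()
def tiny_image():
    """A minimal valid FundusImage for plumbing tests."""
    from fundustriage.types import FundusImage
    rng = np.random.default_rng(0)
    return FundusImage(rng.integers(0, 256, (64, 64, 3), dtype=np.uint8))
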