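import numpy as np
import pytest

from dirprop.core import ImageVolume
from dirprop.demons import demons_register
from dirprop.phantom import (
    PhantomSpec,
    body_mask,
    default_deformation,
    generate_per_treatment,
    generate_planning_phantom,
)
from dirprop.preprocess import histogram_match
from dirprop.sfbr import sfbr_register


class PhantomCase:
    """Bundle of one phantom registration case."""

    def __init__(self, spec):
        self.spec = spec
        self.deform = default_deformation(spec, seed=spec.seed + 1)
        self.planning, self.masks = generate_planning_phantom(spec)
        self.per_treatment, self.gt_masks, self.true_dvf = generate_per_treatment(
            self.planning, self.masks, self.deform
        )
        self.body = body_mask(spec)
        self.masks_by_label = {m.label: m for m in self.masks}
        self.gt_by_label = {m.label: m for m in self.gt_masks}


@pytest.fixture(scope="session")
def default_case():
    """Full-size default phantom (96 x 96 x 48 @ 2,2,3 mm), seed 0."""
    return PhantomCase(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def small_case():
    """Same geometry on a coarse grid for cheap end-to-end tests."""
    return PhantomCase(PhantomSpec(dims=(48, 48, 24), spacing=(4.0, 4.0, 6.0), seed=0))


@pytest.fixture(scope="session")
def demons_result(default_case):
    """Demons registration of the default phantom (shared; ~5 s)."""
    matched = histogram_match(default_case.planning, default_case.per_treatment)
    return demons_register(default_case.per_treatment, matched)


@pytest.fixture(scope="session")
def sfbr_result(default_case):
    """SFBR registration of the default phantom (shared; ~5 s)."""
    return sfbr_register(default_case.planning, default_case.per_treatment)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_volume(rng, dims=(6, 5, 4), spacing=(2.0, 2.0, 3.0), origin=(0.0, 0.0, 0.0)):
    return ImageVolume(rng.normal(0, 50, dims), spacing, origin)
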