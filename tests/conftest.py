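"""Shared fixtures: small, fast phantom specs and default parameters."""

from dataclasses import replace

import numpy as np
import pytest

from octrt import PhantomSpec, SegmentationParams


@pytest.fixture
def params():
    return SegmentationParams()


@pytest.fixture
def small_spec():
    """Reduced lateral extent for speed; axial geometry stays realistic."""
    return PhantomSpec(n_bscans=3, n_ascans=48, seed=7)


@pytest.fixture
def noiseless_small_spec(small_spec):
    return replace(small_spec, speckle_k=None)


def random_spec(rng: np.random.Generator, **overrides) -> PhantomSpec:
    """A randomized phantom within the default operating regime."""
    thickness = rng.uniform(150.0, 300.0)
    base = rng.uniform(650.0, 850.0)
    fields = dict(
        n_bscans=2,
        n_ascans=16,
        irl_coeffs=((base, rng.uniform(-5, 5)), (0.0, 0.0), (rng.uniform(0, 20), 0.0)),
        thickness_coeffs=((thickness,),),
        choroid_gap_um=rng.uniform(40.0, 65.0),
        sclera_sigma_um=rng.uniform(12.0, 20.0),
        vitreous_level=rng.uniform(2.0, 8.0),
        retina_level=rng.uniform(50.0, 65.0),
        choroid_level=rng.uniform(18.0, 32.0),
        sclera_level=rng.uniform(140.0, 170.0),
        transition_scale_um=rng.uniform(3.0, 8.0),
        speckle_k=None,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    fields.update(overrides)
    return PhantomSpec(**fields)
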