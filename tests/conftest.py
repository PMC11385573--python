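import numpy as np
import pytest

from paleoseg.annotation import (
    choose_validation_slice,
    derive_negative_ranges,
    make_initial_plan,
)
from paleoseg.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def desk_phantom():
    """The default desk-scale phantom volume with its ground truth."""
    params = PhantomParams(seed=11)
    stack, truth = generate_phantom(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def desk_plan(desk_phantom):
    """Every-10th-slice plan over the phantom's fossil extent."""
    params, stack, truth = desk_phantom
    z0, z1 = params.fossil_range
    plan = make_initial_plan(
        z0, z1 - 1, 10,
        negative_ranges=derive_negative_ranges(truth, stack.n_slices),
    )
    ann = truth.subset(plan.annotated_indices)
    plan.validation_index = choose_validation_slice(ann, "simplest")
    return plan


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
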