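import numpy as np
import pytest

import chs


@pytest.fixture(scope="session")
def small_spec():
    return chs.LandscapeSpec(grid_rows=40, grid_cols=40, seed=11)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return chs.generate_stack(small_spec)


@pytest.fixture(scope="session")
def envelope_species(small_stack):
    sp = chs.VirtualSpecies(response_variables=["bio1"],
                            response_kind="envelope",
                            envelope_bounds={"bio1": (1.0, 99.0)})
    return chs.generate_species(small_stack, sp)


@pytest.fixture(scope="session")
def occurrences(envelope_species, small_stack):
    return chs.sample_occurrences(envelope_species, small_stack, 120, seed=11)
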