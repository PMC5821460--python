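import numpy as np
import pytest

from l1cycle import synthgen
from l1cycle.datatypes import FTKinetics, default_cell_cycle_model


@pytest.fixture(scope="session")
def model():
    return default_cell_cycle_model()


@pytest.fixture(scope="session")
def kinetics():
    return FTKinetics()


@pytest.fixture(scope="session")
def paired_field():
    """Field with planted daughter pairs of nuclear-positive cells."""
    return synthgen.gen_cell_field(
        150, frac_nuclear=0.2, frac_paired=0.8, pair_sep_mean=10.0,
        pair_sep_sd=1.0, width=1000.0, height=1000.0, seed=42,
    )


@pytest.fixture(scope="session")
def random_label_field():
    """Field with uniformly random nuclear labels (no spatial signal)."""
    return synthgen.gen_cell_field(
        150, frac_nuclear=0.2, frac_paired=0.0, width=1000.0, height=1000.0,
        seed=43,
    )


@pytest.fixture(scope="session")
def small_image():
    """Small rendered field with 30% nuclear-positive cells."""
    field = synthgen.gen_cell_field(40, 0.3, 0.0, width=420.0, height=420.0,
                                    seed=7)
    return field, synthgen.gen_image(field, seed=8)


@pytest.fixture(scope="session")
def negative_image():
    """Negative-control bundle: nuclei present, marker not expressed."""
    field = synthgen.gen_cell_field(120, 0.0, 0.0, width=700.0, height=700.0,
                                    seed=9)
    return synthgen.gen_image(
        field, intensity_params=(0.0, 0.0, 50.0, 8.0), seed=10
    )
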