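import numpy as np
import pytest

from mammil.imaging import Label, Laterality, Mammogram, View
from mammil.synthetic import PhantomSpec, generate_dataset


def make_mammogram(
    pixels,
    patient_id="P0",
    laterality=Laterality.LEFT,
    view=View.CC,
    label=Label.NON_CANCER,
    pixel_spacing_mm=0.085,
    bit_depth=12,
):
    return Mammogram(
        pixels=np.asarray(pixels, dtype=np.float64),
        patient_id=patient_id,
        laterality=laterality,
        view=view,
        pixel_spacing_mm=pixel_spacing_mm,
        bit_depth=bit_depth,
        label=label,
    )


@pytest.fixture(scope="session")
def phantom_cases():
    """Small deterministic phantom cohort shared across tests."""
    return generate_dataset(PhantomSpec(n_patients=24, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
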