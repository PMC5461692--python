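import numpy as np
import pytest

from thyrocad import CTImage, PhantomConfig, ROIMask, generate_dataset
from thyrocad.pipeline import extract_feature_table


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_image(rng):
    return CTImage(pixels=rng.uniform(-100, 300, (16, 16)), source_id="rand16")


@pytest.fixture(scope="session")
def small_cohort():
    """20 normal + 20 nodule phantoms, in memory, with all four filter groups."""
    manifest, triples = generate_dataset(PhantomConfig(), 20, 20, seed=101)
    samples = [(img, mask, label, f"s{i}", manifest["patient_id"][i])
               for i, (img, mask, label) in enumerate(triples)]
    return extract_feature_table(samples)


def roi_from_values(values, **kw):
    from thyrocad import ROISample

    return ROISample(values=np.asarray(values, dtype=float), **kw)
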