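import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import growthrisk as gr

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def refs():
    """Synthetic LMS reference set covering 0-30 months."""
    return gr.synthetic_reference(seed=0)


@pytest.fixture(scope="session")
def eq3_cohort():
    """Mid-sized cohort drawn from the published eq3 base model."""
    return gr.simulate_model_mode(gr.bib_preset("eq3", n=20_000, seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for bootstrap/stepwise tests."""
    return gr.simulate_model_mode(gr.bib_preset("eq3", n=3_000, seed=12))


@pytest.fixture()
def ref_csv(tmp_path, refs):
    path = tmp_path / "ref.csv"
    refs.save(path)
    return path
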