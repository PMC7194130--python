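import numpy as np
import pytest

import summitveg as sv
from summitveg.synthetic import DEFAULT_SUMMITS


@pytest.fixture(scope="session")
def summit_table():
    return [sv.Summit(s, e) for s, e in DEFAULT_SUMMITS]


@pytest.fixture(scope="session")
def default_survey():
    """One default-design synthetic survey reused by read-only tests."""
    return sv.generate_survey(sv.SurveyDesign(seed=42))


@pytest.fixture
def tiny_observations():
    """Two quadrats, two years, hand-written covers."""
    mk = sv.QuadratObservation
    return [
        mk("GUL1", "N", 1, 2014, "spA", 30.0),
        mk("GUL1", "N", 1, 2014, "spB", 20.0),
        mk("GUL1", "N", 2, 2014, "spA", 10.0),
        mk("GUL1", "N", 2, 2014, "spC", 5.0),
        mk("GUL1", "N", 1, 2018, "spA", 25.0),
        mk("GUL1", "N", 1, 2018, "spB", 22.0),
        mk("GUL1", "N", 2, 2018, "spA", 12.0),
        mk("GUL1", "N", 2, 2018, "spC", 6.0),
    ]


def random_incidence(rng: np.random.Generator, n_sites: int, n_species: int) -> np.ndarray:
    """Random incidence matrix with every site non-empty."""
    while True:
        m = rng.random((n_sites, n_species)) < rng.uniform(0.2, 0.8)
        if m.any(axis=1).all():
            return m
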