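import numpy as np
import pytest

import exomatch as em


@pytest.fixture(scope="session")
def worked():
    """The fixed three-gene micro-dataset plus its proteome counts."""
    fx = em.worked_example()
    return fx, em.count_isoform_aas(fx.records)


@pytest.fixture(scope="session")
def ratios():
    """Packaged FLYAA / MALEAA / FEMALEAA molar-ratio table."""
    return em.reference_diet_ratios()


@pytest.fixture(scope="session")
def small_fixture():
    """A seeded synthetic proteome small enough for fast tests."""
    spec = em.FixtureSpec(seed=20, n_genes=40, length_range=(50, 200), n_replicates=3)
    fx = em.generate(spec)
    return fx, em.count_isoform_aas(fx.records)


def random_profile(rng: np.random.Generator, label: str = "") -> em.AAProfile:
    v = rng.dirichlet(np.ones(len(em.AMINO_ACIDS)))
    return em.AAProfile(v, label)
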