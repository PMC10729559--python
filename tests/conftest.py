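import numpy as np
import pytest

from aimkit.synthetic_population import PopModel, generate_dataset, variant_layout


@pytest.fixture(scope="session")
def small_dataset():
    """Small three-population cohort shared by read-only tests."""
    model = PopModel(n_variants=800, n_alg_train=20, n_m_train=12,
                     n_c_train=16, n_alg_test=8, n_m_test=5, n_c_test=6,
                     missing_rate=0.01, het_artifact_rate=0.002,
                     seed=101)
    return generate_dataset(model)


@pytest.fixture(scope="session")
def toy_variants():
    """2k variants scattered over the default 16-chromosome genome."""
    rng = np.random.default_rng(7)
    return variant_layout(2000, PopModel().chrom_lengths, rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
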