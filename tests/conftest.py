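import pandas as pd
import pytest

from vinemites.experiments import study_analysis_table
from vinemites.simulate import (
    SyntheticConfig,
    generate_study,
    reference_ingredients,
    reference_products,
)


@pytest.fixture(scope="session")
def study():
    """A full default-sized synthetic study (16 pairs, fixed seed)."""
    return generate_study(seed=7)


@pytest.fixture(scope="session")
def analysis_table(study):
    """The study pushed through toxicity/density/landscape assembly."""
    return study_analysis_table(study)


@pytest.fixture(scope="session")
def ingredients():
    return reference_ingredients()


@pytest.fixture(scope="session")
def products():
    return reference_products()


def make_spray(rows):
    """Spray table from (vineyard, date, product, dose, category) tuples."""
    return pd.DataFrame(
        rows,
        columns=["vineyard_id", "date", "product", "dose_g_per_ha", "category"],
    )


@pytest.fixture()
def small_config():
    return SyntheticConfig(n_pairs=4, seed=123)
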