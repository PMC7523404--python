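import numpy as np
import pytest

from commonbase import GroupedData, fit_ols, example_table


@pytest.fixture(scope="session")
def hormone_fit():
    """Case A regression of the tight hormone dataset (table 1)."""
    t = example_table(1)
    return fit_ols(t["hormone_pg_ml"], t["delta_cq_w"])


@pytest.fixture(scope="session")
def hormone_noisy_fit():
    """Case A regression of the noisier hormone dataset (table 2)."""
    t = example_table(2)
    return fit_ols(t["hormone_pg_ml"], t["delta_cq_w"])


@pytest.fixture(scope="session")
def huddling_fit():
    """Case B regression: huddling time on dCq(w) (table 4)."""
    t = example_table(4)
    return fit_ols(t["delta_cq_w"], t["huddling_min"])


@pytest.fixture(scope="session")
def gene_gene_fit():
    """Case C regression: gene B dCq(w) on gene A dCq(w) (table 5)."""
    t = example_table(5)
    return fit_ols(t["delta_cq_a"], t["delta_cq_b"])


@pytest.fixture(scope="session")
def density_fit():
    """Case D regression: dCq(w) on log10 bacterial density (table 6)."""
    t = example_table(6)
    return fit_ols(np.log10(t["cells_per_nl"]), t["delta_cq_w"])


@pytest.fixture(scope="session")
def larval_fit():
    """Case E regression: log10 larval length on dCq(w) (table 7)."""
    t = example_table(7)
    return fit_ols(t["delta_cq_w"], np.log10(t["length_mm"]))


@pytest.fixture(scope="session")
def diet_data():
    """Grouped diet/temperature ANCOVA dataset (table 8)."""
    return GroupedData.from_dataframe(
        example_table(8), x_col="temperature_c", y_col="delta_cq"
    )
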