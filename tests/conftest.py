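import numpy as np
import pandas as pd
import pytest

from aimix.panel_io import ParentalPanel
from aimix.simulate import PanelSimConfig, simulate_panel


@pytest.fixture
def tiny_panel() -> ParentalPanel:
    """Three handmade SNPs with simple frequencies."""
    return ParentalPanel(
        pd.DataFrame(
            {
                "snp_id": ["rs1", "rs2", "rs3"],
                "chrom": ["1", "1", "2"],
                "pos": [1000, 2_000_000, 500],
                "allele1": ["A", "T", "G"],
                "allele2": ["G", "C", "A"],
                "p_eu": [0.9, 0.8, 0.5],
                "p_ai": [0.6, 0.6, 0.5],
                "p_af": [0.1, 0.2, 0.5],
            }
        )
    )


@pytest.fixture(scope="session")
def small_panel() -> ParentalPanel:
    """A 12-SNP balanced synthetic panel for fast estimator checks."""
    return simulate_panel(PanelSimConfig(set_sizes=(4, 4, 4)), seed=101)


@pytest.fixture(scope="session")
def balanced_panel() -> ParentalPanel:
    """The default 1300-SNP balanced synthetic panel (450/450/400)."""
    return simulate_panel(seed=2024)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
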