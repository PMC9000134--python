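import numpy as np
import pytest

from ppidisp import synth

# The published per-property report values (printed precision), keyed by
# (dataset, property): T-group 4 columns then P-group 4 columns
# (pct_T|N, pct_T|M, ratio, pct_N|T, pct_P|N, pct_P|M, ratio, pct_N|P).
PRINTED_TABLE2 = {
    ("Y2H", "strength"): (0.3, 2.0, 0.15, 6.6, 1.2, 10.3, 0.12, 5.6),
    ("Lit", "strength"): (0.9, 3.2, 0.28, 12.9, 1.0, 4.3, 0.23, 10.6),
    ("Y2H", "temporal"): (0.6, 5.2, 0.12, 6.0, 0.8, 6.9, 0.12, 5.8),
    ("Lit", "temporal"): (0.6, 3.6, 0.17, 7.3, 1.4, 3.9, 0.36, 15.5),
    ("Y2H", "spatial_expr"): (0.4, 3.6, 0.11, 5.0, 0.7, 5.7, 0.12, 5.5),
    ("Lit", "spatial_expr"): (0.7, 3.9, 0.18, 8.0, 1.0, 3.1, 0.32, 14.2),
    ("Y2H", "spatial_promoter"): (0.3, 6.7, 0.04, 2.1, 1.2, 4.9, 0.24, 11.1),
    ("Lit", "spatial_promoter"): (0.7, 3.6, 0.19, 8.5, 1.1, 3.8, 0.29, 13.0),
    ("Y2H", "balance_time"): (0.1, 2.3, 0.04, 2.0, 1.4, 9.8, 0.14, 6.7),
    ("Lit", "balance_time"): (0.4, 2.0, 0.20, 9.5, 1.5, 5.4, 0.28, 12.6),
    ("Y2H", "balance_space_expr"): (1.0, 6.1, 0.16, 7.8, 0.5, 5.0, 0.10, 4.5),
    ("Lit", "balance_space_expr"): (1.1, 3.7, 0.30, 13.3, 0.8, 3.6, 0.22, 10.3),
    ("Y2H", "balance_space_promoter"): (0.6, 6.4, 0.09, 4.2, 0.9, 4.9, 0.18, 8.7),
    ("Lit", "balance_space_promoter"): (0.8, 3.1, 0.26, 11.3, 1.0, 4.3, 0.23, 10.8),
    ("Y2H", "exclusivity_1_4"): (0.4, 6.9, 0.06, 2.7, 0.2, 2.3, 0.09, 4.0),
    ("Lit", "exclusivity_1_4"): (1.0, 3.2, 0.31, 14.3, 0.3, 2.2, 0.14, 7.6),
    ("Y2H", "exclusivity_ge5"): (0.8, 3.2, 0.25, 11.9, None, None, None, None),
    ("Lit", "exclusivity_ge5"): (0.5, 1.9, 0.26, 11.9, None, None, None, None),
}


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic synthetic bundle shared across tests."""
    return synth.generate_bundle(synth.GeneratorConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
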