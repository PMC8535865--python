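import numpy as np
import pytest

from epistasis_dili import make_cohort_dataset, make_epistasis_dataset

# Published contingency tables (a = exposed acute, b = exposed chronic,
# c = other acute, d = other chronic) with the printed OR / CI / p columns.
PRINTED_TABLES = {
    "rs6487213": (76, 20, 162, 13),
    "rs5417": (74, 19, 164, 14),
    "rs7658048": (113, 18, 125, 15),
    "rs12453290": (105, 19, 133, 14),
    "rs3785157": (106, 18, 132, 15),
    "mars_pair": (32, 14, 206, 19),
    "mdr_triple": (12, 6, 226, 27),
    "rflr_pair": (36, 10, 202, 23),
}
PRINTED_OR = {
    "rs6487213": 3.28,
    "rs5417": 3.01,
    "rs7658048": 1.33,
    "rs12453290": 1.72,
    "rs3785157": 1.49,
    "mars_pair": 4.74,
    "mdr_triple": 4.19,
    "rflr_pair": 2.44,
}
PRINTED_CI = {
    "rs6487213": (1.57, 7.09),
    "rs5417": (1.44, 6.43),
    "rs7658048": (0.64, 2.79),
    "rs12453290": (0.83, 3.65),
    "rs3785157": (0.72, 3.14),
    "mars_pair": (2.14, 10.39),
    "mdr_triple": (1.36, 11.74),
    "rflr_pair": (1.03, 5.45),
}
# printed p-values; the mars_pair row is printed as "< 0.001"
PRINTED_P = {
    "rs6487213": 0.002,
    "rs5417": 0.004,
    "rs7658048": 0.448,
    "rs12453290": 0.149,
    "rs3785157": 0.282,
    "mdr_triple": 0.008,
    "rflr_pair": 0.034,
}


@pytest.fixture(scope="session")
def epistasis_data():
    """Planted-interaction 250 x 25 dataset, seed 1."""
    return make_epistasis_dataset(seed=1)


@pytest.fixture(scope="session")
def cohort_data():
    """Contingency-anchored 271 x 872 cohort, seed 1."""
    return make_cohort_dataset(seed=1)
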