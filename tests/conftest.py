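import numpy as np
import pandas as pd
import pytest

import coldkit as ck


@pytest.fixture(scope="session")
def small_dictionary():
    """Three unambiguous elements, one per key functional class."""
    return ck.MotifDictionary.from_mapping(
        {
            "ABRE": {"pattern": "ACGTG", "class": "hormone"},
            "LTR": {"pattern": "CCGAAA", "class": "stress"},
            "G-box": {"pattern": "CACGTG", "class": "light"},
        }
    )


@pytest.fixture(scope="session")
def full_dictionary():
    return ck.default_dictionary()


@pytest.fixture(scope="session")
def physio_noiseless():
    return ck.gen_physiology(14, (0, 1, 3, 5, 7), 5, noise_cv=0.0, seed=11)


@pytest.fixture(scope="session")
def atlas_191():
    return ck.gen_expression_atlas(191, n_specific_per_tissue=10, n_silent=4, seed=21)


@pytest.fixture
def tiny_gene_map():
    """3 chromosomes x 60 genes with one tandem array and one collinear block."""
    return ck.gen_gene_map(
        3, 60, tandem_arrays=[(0, 5, 3)], collinear_blocks=[(1, 2, 5, 10)],
        n_dispersed=0, seed=31,
    )


def spearman(a, b):
    from scipy.stats import spearmanr

    return spearmanr(a, b).statistic


@pytest.fixture(scope="session")
def ct_table_exact():
    folds = {("A", 12.0): 8.0, ("A", 24.0): 2.0, ("B", 12.0): 2.0, ("B", 24.0): 1.5}
    table = ck.gen_qpcr_cts(["A", "B"], [0, 12, 24], folds, ct_sd=0.0, seed=41)
    return table, folds
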