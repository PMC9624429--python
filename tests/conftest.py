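import numpy as np
import pandas as pd
import pytest

from ribote import rte as rte_mod
from ribote import synthetic
from ribote.synthetic import ConditionDesign


@pytest.fixture(scope="session")
def design():
    return ConditionDesign.default()


@pytest.fixture(scope="session")
def truth(design):
    """600 genes under the study's 12-condition design."""
    return synthetic.simulate_genes(n_genes=600, effect_size_log2=2.0, design=design, seed=11)


@pytest.fixture(scope="session")
def count_tables(truth, design):
    return synthetic.simulate_counts(
        truth, design, sequencing_depth=2e6, dispersion=0.05, seed=12
    )


@pytest.fixture(scope="session")
def rpkm_tables(count_tables):
    mrna, fp = count_tables
    return rte_mod.compute_rpkm(mrna), rte_mod.compute_rpkm(fp)


@pytest.fixture(scope="session")
def rte_matrix(rpkm_tables):
    mrna, fp = rpkm_tables
    return rte_mod.compute_rte(fp, mrna)


@pytest.fixture(scope="session")
def truth_classes(truth):
    return pd.Series({t.gene_id: t.regulation_class for t in truth})


@pytest.fixture(scope="session")
def cds_models(truth):
    return synthetic.simulate_cds(truth, bias_strength=0.5, seed=13)


def make_table(values, lengths, columns, value_kind="raw_counts", genes=None):
    """Small helper: build an ExpressionTable from plain arrays."""
    from ribote.iofmt import ExpressionTable

    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = pd.MultiIndex.from_tuples(columns, names=["condition", "replicate"])
    frame = pd.DataFrame(values, index=genes, columns=cols)
    return ExpressionTable(frame, pd.Series(lengths, index=genes, dtype=float), value_kind)
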