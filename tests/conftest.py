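import numpy as np
import pandas as pd
import pytest

from retinet.io_qc import depth_normalize, qc_filter
from retinet.synth import CellTypeSpec, SimConfig, generate_counts


@pytest.fixture(scope="session")
def small_dataset():
    """Compact 4-type dataset for unit tests (600 genes x 640 cells)."""
    cfg = SimConfig(
        n_genes=600,
        cell_types=[CellTypeSpec(n, 160, 15) for n in
                    ("rods", "bipolar", "macroglia", "microglia")],
        doublet_rate=0.05,
        seed=42,
    )
    return generate_counts(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    filtered = qc_filter(small_dataset.counts, 50, 5)
    nm = depth_normalize(filtered)
    keep = pd.Index(small_dataset.counts.cell_ids).get_indexer(filtered.cell_ids)
    truth = small_dataset.true_type[keep]
    doublet = small_dataset.is_doublet[keep]
    return nm, truth, doublet


def singlet_view(nm, truth, doublet):
    """Restrict a normalized matrix and labels to singlet cells."""
    m = ~doublet
    sub = type(nm)(nm.values[:, m], nm.depth_factors[m], nm.gene_ids,
                   nm.cell_ids[m], nm.cell_meta.loc[m])
    return sub, truth[m]
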