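import numpy as np
import pandas as pd
import pytest

from reids.datamodel import GeneTensor, ProbeIntensityTable


def make_table_df(
    n_genes=2, probesets_per_gene=2, probes_per_set=4, n_arrays=3, intensity=100.0
):
    """Complete long-format table with constant intensities."""
    rows = []
    for g in range(n_genes):
        gene = f"g{g + 1}"
        for s in range(probesets_per_gene):
            ps = f"{gene}_ps{s + 1}"
            for p in range(probes_per_set):
                probe = f"{ps}_p{p + 1}"
                for a in range(n_arrays):
                    rows.append((gene, ps, probe, f"a{a + 1}", intensity))
    return pd.DataFrame(
        rows, columns=["gene_id", "probeset_id", "probe_id", "array_id", "intensity"]
    )


def make_tensor(Y, n_exons=None, gene_id="g1"):
    """GeneTensor from a matrix, with probes split evenly over exons."""
    Y = np.asarray(Y, dtype=float)
    n, J = Y.shape
    n_exons = n_exons or 1
    assert J % n_exons == 0
    m = J // n_exons
    return GeneTensor(
        gene_id=gene_id,
        Y=Y,
        array_ids=tuple(f"a{i + 1:02d}" for i in range(n)),
        probe_ids=tuple(f"p{j + 1:03d}" for j in range(J)),
        probeset_ids=tuple(f"ps{k + 1:02d}" for k in range(n_exons)),
        exon_of_probe=np.repeat(np.arange(n_exons), m),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return ProbeIntensityTable(make_table_df(), is_log2=False)
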