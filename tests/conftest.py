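import numpy as np
import pandas as pd
import pytest

from alfadiv import geno, synthetic


@pytest.fixture
def toy_afm() -> geno.AlleleFrequencyMatrix:
    """3 accessions x 4 markers with one missing cell and one unmapped
    marker."""
    values = np.array([
        [0.2, 0.5, 0.0, 1.0],
        [0.4, np.nan, 0.1, 0.9],
        [0.3, 0.5, 0.2, 0.8],
    ])
    marker_ids = ["m1", "m2", "m3", "m4"]
    mm = pd.DataFrame(
        {"chrom": ["chr1", "chr1", "chr2", None],
         "pos": [100.0, 200.0, 50.0, np.nan]},
        index=pd.Index(marker_ids, name="marker"),
    )
    return geno.AlleleFrequencyMatrix(
        values=values,
        missing_mask=np.isnan(values),
        accession_ids=["a1", "a2", "a3"],
        marker_ids=marker_ids,
        marker_map=mm,
    )


@pytest.fixture
def small_panel():
    """Structured 3-group panel with pool noise, plus grouping."""
    truth = synthetic.simulate_group_frequencies(
        3, 200, 0.1, outlier_fraction=0.05, fst_outlier=0.6, seed=11
    )
    afm, group_of = synthetic.simulate_panel(
        {g: 10 for g in truth.group_labels}, truth, pool_chromosomes=400,
        seed=12,
    )
    return afm, group_of, truth


@pytest.fixture
def balanced_layout():
    """20 accessions x 3 replicates on a 6x10 grid."""
    acc = [f"a{i}" for i in range(20)]
    return synthetic.simulate_trial(
        6, 10, acc, checks_replication={a: 3 for a in acc}, seed=3
    )
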