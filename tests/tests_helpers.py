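"""Small shared builders for test fixtures."""

import numpy as np
import pandas as pd

from wssgwas import GenotypeMatrix, MarkerMap


def make_genotype_matrix(counts, sample_ids, chroms=None, positions=None):
    counts = np.asarray(counts, dtype=float)
    m = counts.shape[1]
    if chroms is None:
        chroms = np.ones(m, dtype=int)
    if positions is None:
        positions = np.arange(1, m + 1) * 10_000
    markers = MarkerMap(
        pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(m)],
                "chromosome": chroms,
                "position_bp": positions,
                "allele_a": "A",
                "allele_b": "B",
            }
        )
    )
    return GenotypeMatrix(counts=counts, sample_ids=list(sample_ids), markers=markers)
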