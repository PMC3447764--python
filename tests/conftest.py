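import numpy as np
import pandas as pd
import pytest

from snppanel.panel import HET, HOM_ALT, HOM_REF, MISSING, SnpPanel


def make_panel(genotypes, chroms=None, cms=None, subpops=None, **acc_kwargs):
    """Hand-build a small panel from a genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_acc, n_mrk = g.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(n_mrk)],
            "chrom": chroms if chroms is not None else ["1"] * n_mrk,
            "cM": cms if cms is not None else np.arange(n_mrk, dtype=float),
            "bp": np.arange(1, n_mrk + 1, dtype=float) * 1000,
        }
    )
    accessions = pd.DataFrame(
        {
            "accession_id": [f"acc{i}" for i in range(n_acc)],
            "subpopulation": subpops if subpops is not None else [np.nan] * n_acc,
            "is_hybrid": acc_kwargs.get("is_hybrid", [False] * n_acc),
            "duplicate_of": acc_kwargs.get("duplicate_of", [np.nan] * n_acc),
        }
    )
    return SnpPanel(g, markers, accessions)


@pytest.fixture
def toy_panel():
    """3 accessions x 4 markers with every call state represented."""
    return make_panel(
        [
            [HOM_REF, HET, HOM_ALT, MISSING],
            [HOM_REF, HOM_REF, HOM_ALT, HOM_REF],
            [HOM_ALT, HET, HOM_ALT, HET],
        ]
    )
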