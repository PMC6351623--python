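import numpy as np
import pandas as pd
import pytest

from dripseq.counting import CountMatrix


def make_meta(strains, n_reps=3):
    rows = [(f"{s}_r{r+1}", s, str(r + 1)) for s in strains
            for r in range(n_reps)]
    return pd.DataFrame(rows, columns=["library_id", "strain", "replicate"]
                        ).set_index("library_id")


def make_matrix(counts, lengths=None, strains=("c", "m"), n_reps=3):
    """CountMatrix from a 2-D array; columns follow make_meta order."""
    counts = np.asarray(counts)
    meta = make_meta(strains, n_reps)
    assert counts.shape[1] == len(meta)
    ids = [f"f{i}" for i in range(counts.shape[0])]
    if lengths is None:
        lengths = pd.Series(1000, index=ids)
    else:
        lengths = pd.Series(lengths, index=ids)
    return CountMatrix(pd.DataFrame(counts, index=ids, columns=meta.index),
                       lengths, meta)


@pytest.fixture
def two_group_meta():
    return make_meta(["c", "m"])
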