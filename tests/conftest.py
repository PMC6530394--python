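import itertools

import numpy as np
import pytest

from fpannet.trees import SpanningTree, make_tree, _prufer_decode


@pytest.fixture(scope="session")
def star16():
    return make_tree("star", 16)


@pytest.fixture(scope="session")
def path16():
    return make_tree("path", 16)


def all_labeled_trees(n):
    """Every labeled tree on n nodes via exhaustive Pruefer enumeration."""
    if n == 2:
        yield SpanningTree(2, ((0, 1),))
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        yield SpanningTree(n, tuple(_prufer_decode(np.array(seq), n)))


def make_panel(data, subject_id="s"):
    from fpannet.connectivity import TimeSeriesPanel

    data = np.asarray(data, dtype=float)
    return TimeSeriesPanel(
        subject_id=subject_id,
        data=data,
        roi_names=[f"roi{i:02d}" for i in range(data.shape[1])],
    )
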