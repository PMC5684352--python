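import math

import numpy as np
import pytest

from costructure import BipartiteLayer, MultilayerPair


@pytest.fixture
def rng():
    return np.random.default_rng(20171113)


def make_layer(incidence, name="layer", rows=None, cols=None):
    incidence = np.asarray(incidence, dtype=np.int8)
    m, p = incidence.shape
    rows = rows or [f"x{i}" for i in range(m)]
    cols = cols or [f"y{j}" for j in range(p)]
    return BipartiteLayer(name, rows, cols, incidence)


def make_pair(inc1, inc2, names=("L1", "L2")):
    l1 = make_layer(inc1, names[0])
    l2 = make_layer(inc2, names[1])
    return MultilayerPair(l1, l2)


def random_layer(rng, m, p, density=0.3, name="layer"):
    return make_layer((rng.random((m, p)) < density).astype(np.int8), name)


def nmi_oracle(counts):
    """Term-by-term normalized mutual information, independent of the package.

    Direct transcription of the Danon confusion-matrix formula with explicit
    Python loops and math.log.
    """
    counts = [list(map(float, row)) for row in counts]
    n = sum(sum(row) for row in counts)
    ni = [sum(row) for row in counts]
    nj = [sum(counts[i][j] for i in range(len(counts))) for j in range(len(counts[0]))]
    numer = 0.0
    for i, row in enumerate(counts):
        for j, nij in enumerate(row):
            if nij > 0:
                numer += nij * math.log(nij * n / (ni[i] * nj[j]))
    denom = 0.0
    for v in ni:
        if v > 0:
            denom += v * math.log(v / n)
    for v in nj:
        if v > 0:
            denom += v * math.log(v / n)
    if denom == 0.0:
        return 1.0
    return -2.0 * numer / denom
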