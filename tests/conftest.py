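import numpy as np
import pytest

from pleurokit import trees as T


def random_tree(rng, n_tips, with_lengths=True, labels=None):
    """Random rooted binary tree by sequential pair joining."""
    labels = labels or ["t%d" % i for i in range(n_tips)]
    nodes = list(labels)
    parts = {}
    for lb in labels:
        parts[lb] = ("%s:%.4f" % (lb, rng.uniform(0.1, 2.0))) if with_lengths else lb
    frags = [parts[lb] for lb in labels]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        if with_lengths:
            frags.append("(%s,%s):%.4f" % (a, b, rng.uniform(0.1, 2.0)))
        else:
            frags.append("(%s,%s)" % (a, b))
    nwk = frags[0]
    if with_lengths:
        nwk = nwk[: nwk.rfind(":")]
    return T.parse_newick(nwk + ";")


def ultrametric_tree(rng, n_tips, labels=None):
    """Random ultrametric tree with Kingman-coalescent node heights
    (pairwise joins, exponential waiting times at rate C(j, 2))."""
    labels = labels or ["t%d" % i for i in range(n_tips)]
    heights = {lb: 0.0 for lb in labels}
    frags = {lb: lb for lb in labels}
    active = list(labels)
    h = 0.0
    while len(active) > 1:
        j = len(active)
        h += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = sorted(rng.choice(j, size=2, replace=False))
        b = active.pop(i2)
        a = active.pop(i1)
        frags[a] = "(%s:%.6f,%s:%.6f)" % (frags[a], h - heights[a], frags[b], h - heights[b])
        heights[a] = h
        active.append(a)
    return T.parse_newick(frags[active[0]] + ";")


@pytest.fixture
def rng():
    return np.random.default_rng(20250928)


@pytest.fixture
def balanced4():
    return T.parse_newick("((A,B),(C,D));")
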