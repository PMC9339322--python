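import numpy as np
import pytest

from gcjump.phylo_core import Phylogeny, newick_from_string


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the standard worked example."""
    return newick_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry():
    return newick_from_string("(A:1,B:1);")


def star_tree(n_tips: int, depth: float = 1.0) -> Phylogeny:
    """Root with ``n_tips`` direct tip children at equal depth."""
    parent = np.concatenate([[-1], np.zeros(n_tips, dtype=int)])
    blen = np.concatenate([[0.0], np.full(n_tips, depth)])
    labels = [None] + [f"s{i}" for i in range(n_tips)]
    return Phylogeny(parent, blen, labels)


def random_binary_tree(n_tips: int, rng: np.random.Generator) -> Phylogeny:
    """Random topology with exponential branch lengths (test helper,
    independent of the package's Yule generator)."""
    parent = [-1]
    blen = [0.0]
    labels: list = [None]
    tips = []
    for c in (1, 2):
        parent.append(0)
        blen.append(float(rng.exponential(0.5)) + 1e-3)
        labels.append(None)
        tips.append(c)
    while len(tips) < n_tips:
        v = int(tips[rng.integers(len(tips))])
        tips.remove(v)
        for _ in range(2):
            parent.append(None)
            blen.append(float(rng.exponential(0.5)) + 1e-3)
            labels.append(None)
            tips.append(len(parent) - 1)
        # children must have parent index < own: rebuild by appending
        parent[-2] = v
        parent[-1] = v
    k = 0
    for v in tips:
        k += 1
        labels[v] = f"t{k}"
    return Phylogeny(np.array(parent), np.array(blen), labels)


def tip_path_lengths(tree: Phylogeny, weights=None):
    """Brute-force shared root-to-MRCA path sums by walking parent chains
    (independent oracle for covariance construction)."""
    w = tree.blen if weights is None else np.asarray(weights, float)
    tips = tree.tip_indices()
    paths = []
    for t in tips:
        chain = []
        v = int(t)
        while v != 0:
            chain.append(v)
            v = int(tree.parent[v])
        paths.append(set(chain))
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = paths[i] & paths[j]
            C[i, j] = sum(w[v] for v in shared)
    return C
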