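import numpy as np
import pandas as pd
import pytest

from commphylo import read_newick


def write_newick(tmp_path, newick, name="tree.nwk"):
    p = tmp_path / name
    p.write_text(newick + "\n")
    return p


@pytest.fixture
def balanced4(tmp_path):
    """((A:1,B:1):1,(C:1,D:1):1); — depth 2, two cherries."""
    return read_newick(write_newick(tmp_path, "((A:1,B:1):1,(C:1,D:1):1);"))


@pytest.fixture
def star3(tmp_path):
    return read_newick(write_newick(tmp_path, "(A:3,B:3,C:3);"))


@pytest.fixture
def tiny_bundle():
    from commphylo import make_fixture
    return make_fixture(paper_scale=False, seed=11)


@pytest.fixture
def community_df():
    """Two quadrats, three species."""
    return pd.DataFrame({
        "plot_id": ["p1", "p1"],
        "grid_row": [0, 0],
        "grid_col": [0, 1],
        "layer": ["tree", "tree"],
        "A": [2, 0], "B": [1, 4], "C": [0, 3],
    })


# ---------------------------------------------------------------------------
# independent oracles (kept brute-force and separate from library internals)


def lca_distance_oracle(phy):
    """d(i,j) = depth(i) + depth(j) − 2·depth(LCA) via explicit ancestor sets."""
    tree = phy.tree
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[parent] + node.edge.length
        depth[node] = d
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    def dist(a, b):
        anc_a = ancestors(leaves[a])
        anc_b = set(ancestors(leaves[b]))
        lca = next(n for n in anc_a if n in anc_b)
        return depth[leaves[a]] + depth[leaves[b]] - 2 * depth[lca]

    labels = sorted(leaves)
    return labels, dist


def brute_mpd(dm, abund, weighting):
    species = [s for s, f in abund.items() if f > 0]
    if len(species) < 2:
        return float("nan")
    num = den = 0.0
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            w = 1.0 if weighting == "occurrence" else abund[a] * abund[b]
            num += w * dm[a, b]
            den += w
    return num / den


def brute_mntd(dm, abund, weighting):
    species = [s for s, f in abund.items() if f > 0]
    if len(species) < 2:
        return float("nan")
    num = den = 0.0
    for a in species:
        nearest = min(dm[a, b] for b in species if b != a)
        w = 1.0 if weighting == "occurrence" else abund[a]
        num += w * nearest
        den += w
    return num / den


def random_community(species, rng, k_max=None):
    k = rng.integers(2, (k_max or len(species)) + 1)
    chosen = rng.choice(len(species), size=k, replace=False)
    return {species[i]: int(rng.integers(1, 10)) for i in chosen}
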