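"""Phylogeny ingestion, validation, distances, covariance, genus collapsing.

The tree is the source of every phylogenetic distance in the pipeline.  Trees
are stored as :class:`dendropy.Tree` objects wrapped in a thin validated
container; pairwise patristic distances are returned as
:class:`skbio.DistanceMatrix` and the Brownian-motion covariance (shared
root-to-ancestor path lengths) as :class:`skbio.stats.distance.DissimilarityMatrix`
(the covariance has a nonzero diagonal, so it cannot be a hollow distance
matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.distance import DissimilarityMatrix

from .errors import FormatError, ValidationError

#: relative spread of root-to-tip depths below which a tree counts as ultrametric
ULTRAMETRIC_RTOL = 1e-6


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, validated for dispersion analysis.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree; every edge except possibly the root seed edge must carry
        a nonnegative length and every tip a unique label.
    """

    tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        # the analysis contract is a rooted tree; the seed node is the root
        self.tree.is_rooted = True
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()
                  if leaf.taxon is not None]
        n_leaves = sum(1 for _ in self.tree.leaf_node_iter())
        if len(labels) != n_leaves:
            raise ValidationError("every tip must carry a taxon label")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise ValidationError(
                    f"missing branch length on edge above {_describe(node)}")
            if node.edge.length < 0:
                raise ValidationError(
                    f"negative branch length ({node.edge.length}) above "
                    f"{_describe(node)}")
        self.tip_labels = labels

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def tip_depths(self) -> pd.Series:
        """Root-to-tip path length for every tip."""
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return pd.Series({leaf.taxon.label: leaf.root_distance
                          for leaf in self.tree.leaf_node_iter()})

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        return float(self.tip_depths().max())

    @property
    def is_ultrametric(self) -> bool:
        """True if all root-to-tip depths agree to a relative tolerance."""
        d = self.tip_depths().to_numpy()
        dmax = d.max()
        if dmax == 0:
            return True
        return bool((dmax - d.min()) <= ULTRAMETRIC_RTOL * dmax)

    def ultrametric_spread(self) -> float:
        """Relative spread (max−min)/max of root-to-tip depths."""
        d = self.tip_depths().to_numpy()
        return float((d.max() - d.min()) / d.max()) if d.max() > 0 else 0.0

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))


def _describe(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return f"tip '{node.taxon.label}'"
    return f"internal node with {len(node.leaf_nodes())} descendant tips"


def read_newick(path) -> Phylogeny:
    """Read a single rooted newick tree with mandatory branch lengths.

    Quoted labels and square-bracket comments are accepted; internal node
    labels are ignored.  A parse failure raises :class:`FormatError` naming
    the offending token; duplicate tips or missing branch lengths raise
    :class:`ValidationError`.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        if "Duplicate" in type(exc).__name__ or "Multiple occurrences" in str(exc):
            raise ValidationError(f"duplicate tip labels in {path}: {exc}") from exc
        raise FormatError(f"could not parse newick file {path}: {exc}") from exc
    phy = Phylogeny(tree)
    if phy.n_tips < 2:
        warnings.warn(
            "tree has fewer than 2 tips; unusable for dispersion analysis",
            stacklevel=2)
    if not phy.is_ultrametric:
        warnings.warn(
            f"tree is not ultrametric (relative depth spread "
            f"{phy.ultrametric_spread():.3g}); dated-distance analyses assume "
            "an ultrametric tree", stacklevel=2)
    return phy


def cophenetic_distances(phy: Phylogeny) -> DistanceMatrix:
    """Patristic (path-length) distance between every pair of tips.

    d(i, j) is the sum of branch lengths on the path from tip i to tip j.
    """
    if phy.n_tips < 2:
        raise ValidationError("need at least 2 tips for pairwise distances")
    pdm = phy.tree.phylogenetic_distance_matrix()
    taxa = sorted(phy.tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(out, ids=[t.label for t in taxa])


def phylo_vcv(phy: Phylogeny) -> DissimilarityMatrix:
    """Brownian-motion covariance structure of the tips.

    V[i, j] is the root-to-MRCA path length shared by tips i and j;
    V[i, i] is the root-to-tip depth of i.  For an ultrametric tree
    d(i, j) = V_ii + V_jj − 2 V_ij.
    """
    tree = phy.tree
    if tree.seed_node is None:
        raise ValidationError("tree has no root; root it before computing V")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    labels = sorted(phy.tip_labels)
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    # postorder: each internal node is the MRCA of tip pairs drawn from
    # different child subtrees
    tips_below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = index[node.taxon.label]
            V[k, k] = node.root_distance
            tips_below[node] = [k]
        else:
            groups = [tips_below.pop(c) for c in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.asarray(groups[a])
                    ib = np.asarray(groups[b])
                    V[np.ix_(ia, ib)] = node.root_distance
                    V[np.ix_(ib, ia)] = node.root_distance
            tips_below[node] = [k for g in groups for k in g]
    return DissimilarityMatrix(V, ids=labels)


def read_genus_map(path) -> dict[str, str]:
    """Two-column CSV ``species_id,genus_id`` → mapping."""
    df = pd.read_csv(path)
    expected = ["species_id", "genus_id"]
    if list(df.columns) != expected:
        raise FormatError(
            f"genus map must have header {expected!r}, got {list(df.columns)!r}")
    if df["species_id"].duplicated().any():
        dupes = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise ValidationError(f"species mapped to more than one genus: {dupes}")
    return dict(zip(df["species_id"], df["genus_id"]))


def genus_level_tree(phy: Phylogeny, genera: Mapping[str, str]) -> Phylogeny:
    """Collapse congeneric tips to a polytomy at the genus MRCA's age.

    For every genus with two or more tips, the congeners are reattached as a
    single polytomy whose node sits at the age of the genus's most recent
    common ancestor in the input tree, so all species within a genus carry the
    same node age.  Monotypic genera are untouched.  A genus whose members are
    not monophyletic is collapsed at the MRCA of all its members, with a
    warning (the MRCA subtree then also contains other genera, which keep
    their positions).
    """
    missing = [t for t in phy.tip_labels if t not in genera]
    if missing:
        raise ValidationError(f"tips missing from genus map: {sorted(missing)}")

    out = phy.clone()
    tree = out.tree
    genus_tips: dict[str, list[str]] = {}
    for t in out.tip_labels:
        genus_tips.setdefault(genera[t], []).append(t)

    for genus, members in sorted(genus_tips.items()):
        if len(members) < 2:
            continue
        tree.calc_node_root_distances(return_leaf_distances_only=False)
        leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        nodes = [leaves[m] for m in members]
        mrca = tree.mrca(taxa=[nd.taxon for nd in nodes])
        under = {lf.taxon.label for lf in mrca.leaf_iter()}
        if under != set(members):
            warnings.warn(
                f"genus '{genus}' is not monophyletic; collapsing at the MRCA "
                f"of its {len(members)} members (subtree also spans "
                f"{len(under) - len(members)} other tips)", stacklevel=2)
        tip_depth = {m: leaves[m].root_distance for m in members}
        for m in members:
            leaves[m].parent_node.remove_child(leaves[m])
        _drop_empty_branches(tree, keep=mrca)
        for m in members:
            child = tree.node_factory()
            child.taxon = tree.taxon_namespace.get_taxon(m)
            mrca.add_child(child)
            child.edge.length = tip_depth[m] - mrca.root_distance
        tree.suppress_unifurcations()
    return Phylogeny(tree)


def _drop_empty_branches(tree: dendropy.Tree, keep: dendropy.Node) -> None:
    """Remove childless internal nodes left behind by leaf detachment."""
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder_node_iter()):
            if node.taxon is None and not node.child_nodes() and node is not keep \
                    and node.parent_node is not None:
                node.parent_node.remove_child(node)
                changed = True
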