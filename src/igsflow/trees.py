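"""Counting high-supported major clusters in per-sample variant trees.

A sample's unique amplicon variants, placed on a phylogram with bootstrap
supports, group into a number of well-supported clusters that serves as a
proxy for the number of distinct ribotype lineages (and, cautiously, rDNA
loci) in that genome.  The counter scans the (midpoint-rooted, if the input
is unrooted) tree top-down: a major cluster is a maximal clade with support
>= ``min_support`` and at least ``min_size`` tips none of whose ancestors
already qualified; supported clades nested inside a major cluster are
reported separately as sub-clusters; tips under no qualifying clade are
singleton outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy

from .errors import FormatError, IgsflowError


@dataclass
class ClusterReport:
    sample_id: str
    n_major_clusters: int
    clusters: list[list[str]]
    nested_clusters: list[list[str]]
    singleton_outliers: list[str]
    support_threshold: float
    min_cluster_size: int

    @property
    def n_tips(self) -> int:
        return sum(len(c) for c in self.clusters) + len(self.singleton_outliers)


def _support_of(node: dendropy.Node) -> float:
    label = node.label
    if label is None:
        return 0.0
    try:
        value = float(label)
    except ValueError as exc:
        raise FormatError(f"internal node label {label!r} is not a support value") from exc
    if not 0.0 <= value <= 100.0:
        raise FormatError(f"support {value} outside [0, 100]")
    return value


def _tip_labels(node: dendropy.Node) -> list[str]:
    return [
        leaf.taxon.label if leaf.taxon else (leaf.label or "?")
        for leaf in node.leaf_iter()
    ]


def count_major_clusters(
    tree: dendropy.Tree | str | Path,
    min_support: float = 70.0,
    min_size: int = 2,
    sample_id: str = "",
    midpoint: bool = True,
) -> ClusterReport:
    """Count maximal high-supported clades of >= ``min_size`` tips.

    Accepts a dendropy tree or a newick path with supports as internal node
    labels (missing labels are treated as support 0).  Unrooted trees
    (root of degree > 2) are midpoint-rooted first when branch lengths are
    available; the two clades flanking the new root describe the same
    bipartition, so they share the larger of their two labels.
    """
    if not isinstance(tree, dendropy.Tree):
        try:
            tree = dendropy.Tree.get(
                path=str(tree),
                schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise FormatError(f"could not parse newick tree: {exc}") from exc
    else:
        tree = tree.clone(depth=1)

    root = tree.seed_node
    has_lengths = any(e.length for e in tree.preorder_edge_iter())
    if midpoint and len(root.child_nodes()) > 2 and has_lengths:
        # Unrooted phylogram.  Supports belong to edge splits, not to the
        # arbitrary serialisation orientation, so record them per split
        # before rerooting and reassign afterwards.
        all_leaves = frozenset(_tip_labels(root))
        split_support: dict[frozenset, float] = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is root:
                continue
            ls = frozenset(_tip_labels(node))
            s = _support_of(node)
            split_support[ls] = s
            split_support[all_leaves - ls] = s
        tree.reroot_at_midpoint(update_bipartitions=False)
        # If the midpoint effectively coincides with an internal node (a
        # star-like backbone), root at that node instead of keeping a
        # hair-thin subdivision next to it.
        kids = tree.seed_node.child_nodes()
        if len(kids) == 2:
            lens = [(k.edge.length or 0.0) for k in kids]
            total = sum(lens)
            if total > 0:
                for kid, ln in zip(kids, lens):
                    if not kid.is_leaf() and ln < 0.25 * total:
                        tree.reroot_at_node(kid, update_bipartitions=False)
                        tree.suppress_unifurcations()
                        break
        root = tree.seed_node
        root.label = None  # the full tip set is no split; never a cluster
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is root:
                continue
            ls = frozenset(_tip_labels(node))
            node.label = repr(split_support.get(ls, 0.0))

    clusters: list[list[str]] = []
    nested: list[list[str]] = []
    singletons: list[str] = []

    def _height(node: dendropy.Node) -> tuple[float, float]:
        """(height, diameter) of the subtree below ``node``."""
        if node.is_leaf():
            return 0.0, 0.0
        best = [0.0, 0.0]  # two largest child heights
        diam = 0.0
        for child in node.child_nodes():
            h, d = _height(child)
            h += child.edge.length or 0.0
            diam = max(diam, d)
            if h > best[0]:
                best = [h, best[0]]
            elif h > best[1]:
                best[1] = h
        return best[0], max(diam, best[0] + best[1])

    def _cohesive_root_child(node: dendropy.Node) -> bool:
        """A root child's split support attests the tighter side of the root
        bipartition; only a child whose subtree is compact relative to its
        subtending branch reads that support as its own cohesion."""
        if not has_lengths:
            return True
        edge_len = node.edge.length or 0.0
        if edge_len == 0.0:
            return True
        _, diam = _height(node)
        return diam <= 2.0 * edge_len

    def scan(node: dendropy.Node, inside_major: bool) -> None:
        if node.is_leaf():
            if not inside_major:
                singletons.append(_tip_labels(node)[0])
            return
        support = _support_of(node)
        tips = _tip_labels(node)
        qualifies = support >= min_support and len(tips) >= min_size
        if qualifies and node.parent_node is root and not _cohesive_root_child(node):
            qualifies = False
        if qualifies and not inside_major:
            clusters.append(tips)
            inside_major = True
        elif qualifies and inside_major:
            nested.append(tips)
        for child in node.child_nodes():
            scan(child, inside_major)

    scan(root, False)
    return ClusterReport(
        sample_id=sample_id,
        n_major_clusters=len(clusters),
        clusters=clusters,
        nested_clusters=nested,
        singleton_outliers=singletons,
        support_threshold=min_support,
        min_cluster_size=min_size,
    )
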