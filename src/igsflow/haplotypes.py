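"""Plastid haplotype collapse, diversity statistics, median-joining network.

Haplotypes are aligned sequences compared treating the gap '-' as a fifth
character state, so length-variant individuals separate even when their
bases agree.  Haplotype diversity is Nei's corrected heterozygosity
``Hd = n/(n-1) * (1 - sum p_i^2)``.  The network is built in the
median-joining spirit: an epsilon-relaxed minimum-spanning network over the
current node set (Hamming distance, all character changes weight 1),
augmented by majority-consensus median vectors of near-connected node
triples whenever adding one strictly reduces the total spanning cost,
with degree-<3 median nodes pruned at the end.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AlignmentError, IgsflowError
from .seqio import SequenceRecord


def hamming(a: str, b: str) -> int:
    """Number of differing positions; gaps count as a fifth state."""
    if len(a) != len(b):
        raise AlignmentError("hamming distance requires equal lengths")
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def _dist_matrix(seqs: Sequence[str]) -> np.ndarray:
    mat = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(np.int64)


# ---------------------------------------------------------------------------
# Collapse and diversity


@dataclass
class HaplotypeSet:
    """Unique haplotypes with per-taxon counts and individual assignments."""

    haplotypes: list[str]
    counts: pd.DataFrame  # haplotype label x taxon, integer counts
    assignment: dict[str, str]  # individual id -> haplotype label

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    def sequence_of(self, label: str) -> str:
        return self.haplotypes[self.labels.index(label)]

    def h_tot(self, taxon: str) -> int:
        return int((self.counts[taxon] > 0).sum())

    def h_sh(self, taxon: str) -> int:
        """Haplotypes of ``taxon`` also observed in at least one other taxon."""
        here = self.counts[taxon] > 0
        elsewhere = self.counts.drop(columns=[taxon]).sum(axis=1) > 0
        return int((here & elsewhere).sum())

    def hd(self, taxon: str) -> float:
        return haplotype_diversity(
            [int(c) for c in self.counts[taxon] if c > 0]
        )

    def stats_frame(self) -> pd.DataFrame:
        taxa = list(self.counts.columns)
        rows = []
        for t in taxa:
            n = int(self.counts[t].sum())
            rows.append(
                {
                    "taxon": t,
                    "n": n,
                    "h_tot": self.h_tot(t),
                    "h_sh": self.h_sh(t),
                    "hd": self.hd(t) if n >= 2 else math.nan,
                }
            )
        return pd.DataFrame(rows).set_index("taxon")


def collapse_haplotypes(
    records: Sequence[SequenceRecord], taxon_of: Mapping[str, str]
) -> HaplotypeSet:
    """Collapse aligned individuals into haplotypes by exact identity
    (gap as a fifth state); count per taxon."""
    lengths = {len(r) for r in records}
    if len(lengths) > 1:
        raise AlignmentError("haplotype collapse requires an alignment")
    for r in records:
        if r.id not in taxon_of:
            raise IgsflowError(f"individual {r.id!r} has no taxon assignment")
    seq_to_inds: dict[str, list[str]] = {}
    for r in records:
        seq_to_inds.setdefault(r.seq, []).append(r.id)
    totals = {s: len(ids) for s, ids in seq_to_inds.items()}
    haplotypes = sorted(seq_to_inds, key=lambda s: (-totals[s], s))
    labels = [f"H{i + 1}" for i in range(len(haplotypes))]
    taxa: list[str] = []
    for r in records:
        t = taxon_of[r.id]
        if t not in taxa:
            taxa.append(t)
    counts = pd.DataFrame(0, index=labels, columns=taxa, dtype=np.int64)
    assignment: dict[str, str] = {}
    for label, seq in zip(labels, haplotypes):
        for ind in seq_to_inds[seq]:
            assignment[ind] = label
            counts.loc[label, taxon_of[ind]] += 1
    return HaplotypeSet(haplotypes=haplotypes, counts=counts, assignment=assignment)


def haplotype_diversity(counts: Iterable[int]) -> float:
    """Nei's haplotype diversity with the n/(n-1) small-sample correction."""
    counts = [int(c) for c in counts]
    n = sum(counts)
    if n < 2:
        raise IgsflowError("haplotype diversity needs >= 2 individuals")
    freqs = [c / n for c in counts]
    return (n / (n - 1)) * (1.0 - sum(p * p for p in freqs))


# ---------------------------------------------------------------------------
# Median-joining network


def _union_find(n: int):
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    return find, union


def minimum_spanning_network(
    seqs: Sequence[str], epsilon: int = 0
) -> list[tuple[int, int, int]]:
    """Edges (i, j, weight) of the epsilon-relaxed minimum spanning network.

    An edge of weight w joins nodes not already connected using only edges
    of weight < w - epsilon; with epsilon 0 this is the classic MSN (all
    minimum-spanning trees overlaid).
    """
    n = len(seqs)
    D = _dist_matrix(seqs)
    pairs = [(int(D[i, j]), i, j) for i in range(n) for j in range(i + 1, n)]
    edges: list[tuple[int, int, int]] = []
    for w in sorted({p[0] for p in pairs}):
        find, union = _union_find(n)
        for pw, i, j in pairs:
            if pw < w - epsilon:
                union(i, j)
        for pw, i, j in pairs:
            if pw == w and find(i) != find(j):
                edges.append((i, j, w))
        # note: connectivity for the next level is recomputed from scratch,
        # so ties within a level cannot block each other
    return edges


def _mst_cost(seqs: Sequence[str]) -> int:
    from scipy.sparse.csgraph import minimum_spanning_tree

    if len(seqs) < 2:
        return 0
    D = _dist_matrix(seqs)
    return int(round(minimum_spanning_tree(D.astype(float)).sum()))


def _median(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:  # all three distinct: deterministic lexicographic tie-break
            out.append(min(x, y, z))
    return "".join(out)


@dataclass
class HaplotypeNetwork:
    """Observed haplotypes plus inferred medians with mutation-weighted edges."""

    graph: nx.Graph
    observed: list[str]
    medians: list[str]

    @property
    def total_cost(self) -> int:
        """Weight of a minimum spanning tree over all network nodes."""
        return _mst_cost(list(self.graph.nodes))

    def lineage_groups(self, cut: int = 10) -> list[set[str]]:
        """Groups of observed haplotypes connected by edges of <= ``cut``
        mutations (deep splits in the network are severed)."""
        g = nx.Graph(
            (u, v) for u, v, w in self.graph.edges(data="weight") if w <= cut
        )
        g.add_nodes_from(self.graph.nodes)
        groups = []
        for comp in nx.connected_components(g):
            obs = {s for s in comp if s in set(self.observed)}
            if obs:
                groups.append(obs)
        return sorted(groups, key=lambda g: sorted(g)[0])


def mj_network(
    haps: HaplotypeSet | Sequence[str],
    epsilon: int = 0,
    max_medians: int | None = None,
) -> HaplotypeNetwork:
    """Median-joining network over a set of haplotypes.

    Iteratively adds the majority-consensus median of near-connected node
    triples that most reduces the minimum-spanning cost (lexicographically
    smallest sequence on ties), until no median helps; then prunes inferred
    medians of degree < 3 and returns the epsilon-relaxed MSN over the
    final node set.
    """
    if isinstance(haps, HaplotypeSet):
        observed = list(haps.haplotypes)
        hapset = haps
    else:
        observed = sorted(set(haps))
        hapset = None
    if len(observed) < 2:
        raise IgsflowError("network needs >= 2 haplotypes")
    lengths = {len(s) for s in observed}
    if len(lengths) > 1:
        raise AlignmentError("haplotypes must be aligned to equal length")
    if max_medians is None:
        max_medians = math.comb(len(observed), 3)

    nodes = sorted(observed)
    obs_set = set(observed)
    medians: list[str] = []

    def aug_mst_cost(dmat: np.ndarray, seqs: list[str], extra: str) -> int:
        from scipy.sparse.csgraph import minimum_spanning_tree

        vec = np.array([hamming(extra, s) for s in seqs], dtype=float)
        n = len(seqs)
        full = np.zeros((n + 1, n + 1))
        full[:n, :n] = dmat
        full[:n, n] = vec
        full[n, :n] = vec
        return int(round(minimum_spanning_tree(full).sum()))

    while len(medians) < max_medians:
        dmat = _dist_matrix(nodes).astype(float)
        from scipy.sparse.csgraph import minimum_spanning_tree

        base = int(round(minimum_spanning_tree(dmat).sum()))
        # Candidate medians come from every triple of current nodes; with
        # epsilon 0 the classic near-connected restriction can starve the
        # pool and strand the search in a local minimum on small inputs.
        candidates: set[str] = set()
        for u, v, w in itertools.combinations(range(len(nodes)), 3):
            m = _median(nodes[u], nodes[v], nodes[w])
            if m not in nodes:
                candidates.add(m)
        best: tuple[int, list[str]] | None = None
        for m in sorted(candidates):
            gain = base - aug_mst_cost(dmat, nodes, m)
            if gain > 0 and (best is None or gain > best[0]):
                best = (gain, [m])
        if best is None and len(candidates) <= 60:
            # no single median helps: on small inputs, try coordinated pairs
            # (two medians can open a shortcut neither opens alone)
            for m1, m2 in itertools.combinations(sorted(candidates), 2):
                gain = base - _mst_cost(nodes + [m1, m2])
                if gain > 0 and (best is None or gain > best[0]):
                    best = (gain, [m1, m2])
        if best is None:
            break
        medians.extend(best[1])
        nodes = sorted(nodes + best[1])

    # prune medians that never became true junctions
    while True:
        edges = minimum_spanning_network(nodes, epsilon=epsilon)
        degree = {i: 0 for i in range(len(nodes))}
        for i, j, _ in edges:
            degree[i] += 1
            degree[j] += 1
        drop = [
            nodes[i]
            for i in range(len(nodes))
            if nodes[i] not in obs_set and degree[i] < 3
        ]
        if not drop:
            break
        nodes = [s for s in nodes if s not in set(drop)]
        medians = [m for m in medians if m not in set(drop)]

    edges = minimum_spanning_network(nodes, epsilon=epsilon)
    graph = nx.Graph()
    med_labels: dict[str, str] = {}
    for s in nodes:
        if s in obs_set:
            label = hapset.labels[hapset.haplotypes.index(s)] if hapset else "H?"
            freq = (
                {t: int(c) for t, c in hapset.counts.loc[label].items() if c > 0}
                if hapset
                else {}
            )
            graph.add_node(s, kind="observed", label=label, taxa=freq)
        else:
            med_labels[s] = f"M{len(med_labels) + 1}"
            graph.add_node(s, kind="median", label=med_labels[s], taxa={})
    for i, j, w in edges:
        graph.add_edge(nodes[i], nodes[j], weight=int(w))
    return HaplotypeNetwork(graph=graph, observed=observed, medians=medians)


def mj_network_bruteforce(seqs: Sequence[str]) -> int:
    """Independent oracle: minimum spanning cost over the best subset of
    one-level candidate medians (medians of all observed triples),
    found by exhaustive subset enumeration.  Small inputs only."""
    observed = sorted(set(seqs))
    candidates = sorted(
        {
            _median(a, b, c)
            for a, b, c in itertools.combinations(observed, 3)
        }
        - set(observed)
    )
    if len(candidates) > 16:
        raise IgsflowError(
            "brute-force oracle limited to <= 16 distinct candidate medians"
        )
    best = _mst_cost(observed)
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            cost = _mst_cost(observed + list(subset))
            if cost < best:
                best = cost
    return best


def write_gml(network: HaplotypeNetwork, path) -> None:
    g = nx.Graph()
    for node, data in network.graph.nodes(data=True):
        g.add_node(
            data["label"],
            kind=data["kind"],
            taxa=";".join(f"{t}:{c}" for t, c in sorted(data["taxa"].items())),
        )
    for u, v, w in network.graph.edges(data="weight"):
        g.add_edge(
            network.graph.nodes[u]["label"],
            network.graph.nodes[v]["label"],
            weight=int(w),
        )
    nx.write_gml(g, str(path))
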