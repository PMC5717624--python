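"""Rooted phylogenies and regime-painted (simmap-style) trees.

Trees are stored as flat arrays (parent pointers + branch lengths) for fast
traversal in the likelihood code; Newick/NEXUS parsing, writing and pruning
are delegated to dendropy.  A :class:`SimmapTree` adds per-branch piecewise-
constant regime segments, the representation produced by stochastic character
mapping and consumed by the evolutionary-model likelihoods.
"""

from __future__ import annotations

from functools import cached_property

import dendropy
import numpy as np

__all__ = ["Phylogeny", "SimmapTree"]


class Phylogeny:
    """A rooted tree with branch lengths in time units.

    Parameters
    ----------
    parent : array of int
        Parent index per node, ``-1`` for the root.
    lengths : array of float
        Branch length above each node (ignored for the root).
    labels : list of str or None
        Tip labels; internal nodes may be unlabeled.
    """

    def __init__(self, parent, lengths, labels):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        if not (len(self.parent) == len(self.lengths) == len(self.labels)):
            raise ValueError("parent, lengths and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        nonroot = np.delete(np.arange(self.n_nodes), self.root)
        if np.any(self.lengths[nonroot] <= 0):
            raise ValueError("all non-root branch lengths must be > 0")
        tips = self.tip_indices
        names = [self.labels[i] for i in tips]
        if any(n is None for n in names) or len(set(names)) != len(names):
            raise ValueError("tips must carry unique labels")

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @cached_property
    def children(self):
        ch = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    @cached_property
    def tip_indices(self):
        return np.array([i for i in range(self.n_nodes) if not self.children[i]], dtype=int)

    @cached_property
    def tip_labels(self):
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @cached_property
    def postorder(self):
        """Node indices with children before parents."""
        order, stack, seen = [], [self.root], []
        while stack:
            node = stack.pop()
            seen.append(node)
            stack.extend(self.children[node])
        return list(reversed(seen))

    @cached_property
    def preorder(self):
        return list(reversed(self.postorder))

    def depths(self):
        """Distance from the root to each node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        td = self.depths()[self.tip_indices]
        return bool(np.ptp(td) <= tol * max(td.max(), 1.0))

    def total_length(self) -> float:
        mask = np.ones(self.n_nodes, bool)
        mask[self.root] = False
        return float(self.lengths[mask].sum())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.lengths.copy(), list(self.labels))

    # ----------------------------------------------------------------- shape
    def tips_below(self, tip_order=None):
        """Per node, positions (in ``tip_order``) of the tips descending from it."""
        if tip_order is None:
            tip_order = self.tip_labels
        pos = {lab: k for k, lab in enumerate(tip_order)}
        below = [None] * self.n_nodes
        for v in self.postorder:
            if not self.children[v]:
                below[v] = [pos[self.labels[v]]]
            else:
                acc = []
                for c in self.children[v]:
                    acc.extend(below[c])
                below[v] = acc
        return [np.array(sorted(b), dtype=int) for b in below]

    def mrca_depths(self, tip_order=None):
        """Matrix of root-to-MRCA distances (shared path length) for tip pairs.

        The diagonal holds each tip's own depth.
        """
        if tip_order is None:
            tip_order = self.tip_labels
        n = len(tip_order)
        below = self.tips_below(tip_order)
        depth = self.depths()
        S = np.zeros((n, n))
        for v in self.preorder:
            ch = self.children[v]
            for a in range(len(ch)):
                for b in range(a + 1, len(ch)):
                    ia, ib = below[ch[a]], below[ch[b]]
                    S[np.ix_(ia, ib)] = depth[v]
                    S[np.ix_(ib, ia)] = depth[v]
        tips = {self.labels[i]: i for i in self.tip_indices}
        for k, lab in enumerate(tip_order):
            S[k, k] = depth[tips[lab]]
        return S

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.zeros(len(nodes))
        labels: list = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                labels[i] = nd.taxon.label if nd.taxon is not None else nd.label
        return cls(parent, lengths, labels)

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        tns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        dnodes = {}
        for v in self.preorder:
            if v == self.root:
                dnodes[v] = tree.seed_node
            else:
                nd = dnodes[self.parent[v]].new_child()
                nd.edge.length = float(self.lengths[v])
                dnodes[v] = nd
            if not self.children[v]:
                dnodes[v].taxon = tns.require_taxon(label=self.labels[v])
        return tree

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls.from_dendropy(tree)

    @classmethod
    def list_from_file(cls, path) -> list:
        """Read trees from a file in Newick (one per line) or NEXUS format."""
        with open(path) as fh:
            head = fh.read(2048)
        schema = "nexus" if head.lstrip().lower().startswith("#nexus") else "newick"
        trees = dendropy.TreeList.get(path=str(path), schema=schema,
                                      preserve_underscores=True)
        return [cls.from_dendropy(t) for t in trees]

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(schema="newick", suppress_rooting=True)
        return s.strip()

    def prune_to(self, keep_labels) -> "Phylogeny":
        """Drop all tips not in ``keep_labels``; remaining path lengths are preserved."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"labels not in tree: {sorted(missing)}")
        dtree = self.to_dendropy()
        dtree.retain_taxa_with_labels(sorted(keep))
        dtree.suppress_unifurcations()
        return Phylogeny.from_dendropy(dtree)

    def scaled_to_depth(self, depth: float) -> "Phylogeny":
        """Rescale an ultrametric tree so every root-to-tip path equals ``depth``."""
        d = self.depths()[self.tip_indices]
        out = self.copy()
        out.lengths = self.lengths * (depth / d.mean())
        # absorb numerical jitter into the pendant edges
        newd = out.depths()
        for i in out.tip_indices:
            adj = depth - newd[i]
            if out.lengths[i] + adj <= 0:
                raise ValueError("tree too far from ultrametric to rescale")
            out.lengths[i] += adj
        return Phylogeny(out.parent, out.lengths, out.labels)


class SimmapTree:
    """A phylogeny whose branches are painted with regime segments.

    ``segments[i]`` is the ordered list of ``(state, duration)`` pairs on the
    branch above node ``i``, from the parent end towards the node;
    ``node_states[i]`` is the state at node ``i``.
    """

    _TOL = 1e-9

    def __init__(self, tree: Phylogeny, segments, node_states, validate=True):
        self.tree = tree
        self.segments = [list(s) for s in segments]
        self.node_states = list(node_states)
        if validate:
            self._validate()

    def _validate(self):
        t = self.tree
        if len(self.segments) != t.n_nodes or len(self.node_states) != t.n_nodes:
            raise ValueError("segments/node_states must align with tree nodes")
        for i in range(t.n_nodes):
            if i == t.root:
                if self.segments[i]:
                    raise ValueError("root carries no branch segments")
                continue
            segs = self.segments[i]
            if not segs:
                raise ValueError(f"empty segment list on branch above node {i}")
            total = sum(d for _, d in segs)
            if abs(total - t.lengths[i]) > self._TOL * max(1.0, t.lengths[i]):
                raise ValueError(
                    f"segment durations on node {i} sum to {total}, "
                    f"branch length is {t.lengths[i]}")
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                if s1 == s2:
                    raise ValueError("adjacent segments must differ in regime")
            if segs[0][0] != self.node_states[t.parent[i]]:
                raise ValueError("first segment must match parent state")
            if segs[-1][0] != self.node_states[i]:
                raise ValueError("last segment must match node state")

    @classmethod
    def single_regime(cls, tree: Phylogeny, state) -> "SimmapTree":
        segs = [[] if i == tree.root else [(state, float(tree.lengths[i]))]
                for i in range(tree.n_nodes)]
        return cls(tree, segs, [state] * tree.n_nodes)

    @property
    def states(self):
        out = set(self.node_states)
        for segs in self.segments:
            out.update(s for s, _ in segs)
        return tuple(sorted(out))

    @property
    def n_transitions(self) -> int:
        return sum(len(s) - 1 for s in self.segments if s)

    def total_length(self) -> float:
        return sum(d for segs in self.segments for _, d in segs)

    def to_frame(self):
        """Flat table of segments (node, parent, segment order, state, duration)."""
        import pandas as pd

        rows = []
        for i, segs in enumerate(self.segments):
            label = self.tree.labels[i] or f"node{i}"
            for k, (state, dur) in enumerate(segs):
                rows.append({"node": i, "label": label, "segment": k,
                             "state": state, "duration": dur})
        return pd.DataFrame(rows, columns=["node", "label", "segment",
                                           "state", "duration"])

    def to_annotated_newick(self) -> str:
        """Newick with per-branch regime annotations ``{state,dur:...}``."""
        t = self.tree

        def render(v):
            if t.children[v]:
                inner = ",".join(render(c) for c in t.children[v])
                base = f"({inner})"
            else:
                base = t.labels[v]
            if v == t.root:
                return base
            ann = ":".join(f"{{{s},{d:.10g}}}" for s, d in self.segments[v])
            return f"{base}:{t.lengths[v]:.10g}[&map={ann}]"

        return render(t.root) + ";"

    def state_at(self, node: int, height: float):
        """Regime on the branch above ``node`` at ``height`` time units below
        the parent end of the branch."""
        acc = 0.0
        for state, dur in self.segments[node]:
            acc += dur
            if height <= acc + self._TOL:
                return state
        return self.segments[node][-1][0]

    def tip_path_segments(self, tip_order=None):
        """Per tip, the root-to-tip sequence of (state, start, end) intervals."""
        t = self.tree
        if tip_order is None:
            tip_order = t.tip_labels
        depth = t.depths()
        paths = [None] * t.n_nodes
        paths[t.root] = []
        for v in t.preorder:
            if v == t.root:
                continue
            start = depth[t.parent[v]]
            acc = []
            pos = start
            for state, dur in self.segments[v]:
                acc.append((state, pos, pos + dur))
                pos += dur
            paths[v] = paths[t.parent[v]] + acc
        tips = {t.labels[i]: i for i in t.tip_indices}
        return [paths[tips[lab]] for lab in tip_order]
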