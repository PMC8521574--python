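"""Rooted phylogenetic trees with branch lengths (thin dendropy wrapper).

Branch lengths are expected substitutions per site (amino-acid site for
protein trees, codon site for codon trees). Trees are kept rooted; an
outgroup can be named and used to (re)root.
"""

from __future__ import annotations

import dendropy
import numpy as np


class PhyloTree:
    """A rooted tree with named leaves and nonnegative finite branch lengths."""

    def __init__(self, tree: dendropy.Tree, outgroup: str | None = None):
        self._tree = tree
        self.outgroup = outgroup
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, outgroup: str | None = None) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree, outgroup=outgroup)

    @classmethod
    def from_file(cls, path, outgroup: str | None = None) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), outgroup=outgroup)

    def _validate(self):
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue
            if edge.length is None:
                edge.length = 0.0
            if not np.isfinite(edge.length) or edge.length < 0:
                raise ValueError(f"invalid branch length {edge.length!r}")

    # -- basic accessors ---------------------------------------------------

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def n_edges(self) -> int:
        """Number of edges with a parent (the root's null edge is excluded)."""
        return sum(
            1 for e in self._tree.preorder_edge_iter() if e.tail_node is not None
        )

    def newick(self) -> str:
        return (
            self._tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier=".8f",
            ).strip()
            + "\n"
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1), outgroup=self.outgroup)

    def scaled(self, factor: float) -> "PhyloTree":
        t = self._tree.clone(depth=1)
        for e in t.preorder_edge_iter():
            if e.tail_node is not None and e.length is not None:
                e.length = e.length * factor
        return PhyloTree(t, outgroup=self.outgroup)

    # -- rooting -----------------------------------------------------------

    def rerooted_on_outgroup(self, outgroup: str | None = None) -> "PhyloTree":
        """Root so the named outgroup leaf is a child of the root, splitting
        its terminal edge at the midpoint. No-op if already so rooted."""
        og = outgroup or self.outgroup
        if og is None:
            raise ValueError("no outgroup named; cannot root the tree")
        tree = self._tree.clone(depth=1)
        node = None
        for lf in tree.leaf_node_iter():
            if lf.taxon.label == og:
                node = lf
                break
        if node is None:
            raise ValueError(f"outgroup {og!r} is not a leaf of the tree")
        root = tree.seed_node
        if node.parent_node is root and len(root.child_nodes()) == 2:
            return PhyloTree(tree, outgroup=og)
        length = node.edge.length or 0.0
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
        # split the outgroup edge evenly across the two new root children
        for child in tree.seed_node.child_nodes():
            child.edge.length = length / 2.0
        return PhyloTree(tree, outgroup=og)

    # -- distances ---------------------------------------------------------

    def root_to_tip(self) -> dict[str, float]:
        """Sum of branch lengths from the root to every leaf."""
        depths: dict[int, float] = {id(self._tree.seed_node): 0.0}
        out: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                depths[id(node)] = depths[id(node.parent_node)] + (
                    node.edge.length or 0.0
                )
            if node.is_leaf():
                out[node.taxon.label] = depths[id(node)]
        return out

    # -- traversal support for likelihood code -----------------------------

    def postorder_index(self, focal: str | None = None):
        """Flatten the tree for pruning.

        Returns ``(nodes, children, lengths, leaf_rows, foreground)`` where
        ``nodes`` is a postorder list of integer ids (root last), ``children``
        maps node id -> list of child ids, ``lengths`` maps node id -> branch
        length above it, ``leaf_rows`` maps leaf name -> node id, and
        ``foreground`` is the node id of the focal terminal branch (None if
        no focal given).
        """
        order, children, lengths, leaf_rows = [], {}, {}, {}
        foreground = None
        ids = {}
        for node in self._tree.postorder_node_iter():
            nid = ids.setdefault(id(node), len(ids))
            order.append(nid)
            children[nid] = [ids[id(c)] for c in node.child_nodes()]
            lengths[nid] = node.edge.length or 0.0
            if node.is_leaf():
                leaf_rows[node.taxon.label] = nid
                if focal is not None and node.taxon.label == focal:
                    foreground = nid
        if focal is not None and foreground is None:
            raise ValueError(f"focal leaf {focal!r} not in tree")
        return order, children, lengths, leaf_rows, foreground
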