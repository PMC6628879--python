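"""Rooted phylogenies with branch lengths, backed by dendropy.

The wrapper precomputes, for every edge, the set of tips below it; the
diversity module uses these incidence masks to evaluate Faith PD,
phylogenetic endemism and PhyloSor-family dissimilarities as pure array
operations.
"""

from __future__ import annotations

import os
import warnings

import dendropy
import numpy as np

from ..errors import DroppedDataWarning, TreeParseError


class Phylogeny:
    """A rooted tree over uniquely labelled tips with non-negative lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise TreeParseError("duplicate tip labels")
        self.tips: list[str] = labels
        self._tip_index = {t: i for i, t in enumerate(labels)}
        self._build_edges()

    def _build_edges(self):
        n_tips = len(self.tips)
        lengths: list[float] = []
        masks: list[np.ndarray] = []
        below: dict[int, np.ndarray] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                m = np.zeros(n_tips, dtype=bool)
                m[self._tip_index[node.taxon.label]] = True
            else:
                m = np.zeros(n_tips, dtype=bool)
                for child in node.child_nodes():
                    m |= below[id(child)]
            below[id(node)] = m
            if node.parent_node is None:  # seed node carries no edge
                continue
            length = node.edge.length
            if length is None:
                raise TreeParseError("tree has edges without branch lengths")
            if length < 0:
                raise TreeParseError(f"negative branch length {length}")
            lengths.append(float(length))
            masks.append(m)
        self.edge_lengths = np.asarray(lengths, dtype=float)
        #: (n_edges, n_tips) — True where the tip descends from the edge
        self.edge_tip_masks = (
            np.vstack(masks) if masks else np.zeros((0, n_tips), dtype=bool)
        )

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def tip_indices(self, labels) -> np.ndarray:
        missing = [lab for lab in labels if lab not in self._tip_index]
        if missing:
            raise KeyError(f"species absent from tree: {sorted(missing)}")
        return np.asarray([self._tip_index[lab] for lab in labels], dtype=int)

    def edges_for_incidence(self, incidence: np.ndarray) -> np.ndarray:
        """(n_sites, n_edges) bool: edge is in the site's rooted spanning subtree.

        ``incidence`` is (n_sites, n_tips) over :attr:`tips` order.  An edge
        belongs to a site's subtree iff at least one tip below it is present,
        which includes the full path to the root.
        """
        incidence = np.asarray(incidence, dtype=bool)
        return incidence @ self.edge_tip_masks.T > 0

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def _load(source_kwargs: dict, allow_unit_lengths: bool) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            **source_kwargs,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise TreeParseError(f"newick parse error: {exc}") from exc
    missing = [
        nd
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and nd.edge.length is None
    ]
    if missing:
        if not allow_unit_lengths:
            raise TreeParseError(
                f"{len(missing)} edges have no branch length "
                "(pass allow_unit_lengths=True to substitute 1.0)"
            )
        warnings.warn(
            f"substituted unit length on {len(missing)} edges", DroppedDataWarning, stacklevel=3
        )
        for nd in missing:
            nd.edge.length = 1.0
    return Phylogeny(tree)


def read_tree(path: str | os.PathLike, allow_unit_lengths: bool = False) -> Phylogeny:
    """Parse a rooted newick tree file."""
    return _load({"path": os.fspath(path)}, allow_unit_lengths)


def tree_from_newick(text: str, allow_unit_lengths: bool = False) -> Phylogeny:
    """Parse a rooted newick string."""
    return _load({"data": text}, allow_unit_lengths)
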