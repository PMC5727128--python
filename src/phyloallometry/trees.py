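"""Phylogenetic tree handling: reading/writing tree sets, majority-rule
consensus, and Pagel's-λ phylogenetic covariance matrices.

Trees are rooted with non-negative branch lengths in arbitrary time-like
units. The phylogenetic covariance of two tips is the root-to-MRCA path
length (the shared part of their history); Pagel's λ multiplies the
off-diagonal (shared) entries while leaving each tip's own depth untouched,
interpolating between a star phylogeny (λ=0) and pure Brownian motion (λ=1).
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import TreeParseError, ValidationError

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "read_tree_set",
    "write_tree_set",
    "majority_consensus",
    "lambda_transform",
]


class PhyloTree:
    """A rooted phylogenetic tree with unique tip labels.

    Thin wrapper over a :class:`dendropy.Tree` that enforces the package's
    invariants (unique tips, no unifurcations, branch lengths ≥ 0) and
    provides the covariance-matrix view the regression machinery consumes.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        labels = [leaf.taxon.label.strip() if leaf.taxon else ""
                  for leaf in tree.leaf_node_iter()]
        if any(not lab for lab in labels):
            raise ValidationError("every tip must carry a label")
        dupes = [lab for lab, k in Counter(labels).items() if k > 1]
        if dupes:
            raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(
                    f"negative branch length {edge.length} on edge to "
                    f"{edge.head_node}")
        # normalise whitespace in labels once, at the boundary
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = leaf.taxon.label.strip()
        self._tree = tree

    # -- basic accessors -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips})"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as exc:  # dendropy raises several parse classes
            if "Duplicate taxon" in str(exc):
                raise ValidationError(
                    f"duplicate tip labels in tree: {exc}") from exc
            raise TreeParseError(f"could not parse newick string: {exc}") from exc
        return cls(t)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        )
        return s.strip() + "\n"

    # -- geometry --------------------------------------------------------

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        depths: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                if node.edge.length is None:
                    raise ValidationError(
                        f"missing branch length on path to tip {leaf.taxon.label}")
                d += node.edge.length
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth."""
        return max(self.tip_depths().values())

    def shared_path_matrix(self, order: list[str] | None = None
                           ) -> tuple[list[str], np.ndarray]:
        """Matrix of root-to-MRCA path lengths (Brownian covariance, λ=1)."""
        labels = self.tip_labels if order is None else list(order)
        missing = set(labels) - set(self.tip_labels)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        idx = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))

        node_depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise ValidationError("missing branch length; covariance undefined")
            node_depth[id(node)] = node_depth[id(node.parent_node)] + node.edge.length

        tipsets: dict[int, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                tips = [idx[lab]] if lab in idx else []
                if tips:
                    C[tips[0], tips[0]] = node_depth[id(node)]
            else:
                child_sets = [tipsets[id(c)] for c in node.child_nodes()]
                d = node_depth[id(node)]
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        for i in child_sets[a]:
                            for j in child_sets[b]:
                                C[i, j] = C[j, i] = d
                tips = [i for s in child_sets for i in s]
            tipsets[id(node)] = tips
        return labels, C

    def covariance(self, lam: float = 1.0,
                   order: list[str] | None = None) -> "PhyloCovariance":
        return lambda_transform(self, lam, order=order)


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance under Pagel's λ.

    ``matrix[i, j]`` for i≠j is λ × (shared root-to-MRCA path length of tips
    i and j); the diagonal holds each tip's unscaled root-to-tip depth.
    Positive semi-definite for λ ∈ [0, 1].
    """

    species: list[str]
    matrix: np.ndarray = field(repr=False)
    lam: float = 1.0
    tree_height: float = 0.0

    @property
    def n(self) -> int:
        return len(self.species)


def lambda_transform(tree: PhyloTree, lam: float,
                     order: list[str] | None = None) -> PhyloCovariance:
    """Apply Pagel's λ to a tree's Brownian covariance.

    λ=0 yields a diagonal matrix of tip depths (no phylogenetic signal);
    λ=1 the plain shared-path-length matrix (pure Brownian motion).
    """
    lam = float(lam)
    if not (0.0 <= lam <= 1.0):
        raise ValidationError(f"lambda must lie in [0, 1]; got {lam}")
    labels, C = tree.shared_path_matrix(order=order)
    V = C * lam
    np.fill_diagonal(V, np.diag(C))
    return PhyloCovariance(species=labels, matrix=V, lam=lam,
                           tree_height=float(np.max(np.diag(C))))


# -- tree-set I/O --------------------------------------------------------


def read_tree_set(source: str, format: str = "newick") -> list[PhyloTree]:
    """Read a file containing one or more trees (Newick lines or a Nexus
    TREES block) into a list of :class:`PhyloTree`, preserving order."""
    schema = format.lower()
    if schema not in ("newick", "nexus"):
        raise ValidationError(f"unknown tree format {format!r}")
    try:
        tl = dendropy.TreeList.get(path=source, schema=schema)
    except FileNotFoundError:
        raise
    except Exception as exc:
        if "Duplicate taxon" in str(exc):
            raise ValidationError(
                f"duplicate tip labels in {source}: {exc}") from exc
        raise TreeParseError(
            f"could not parse {source} as {schema}: {exc}") from exc
    if len(tl) == 0:
        raise TreeParseError(f"no trees found in {source}")
    return [PhyloTree(t) for t in tl]


def write_tree_set(trees: list[PhyloTree], path: str,
                   format: str = "newick") -> None:
    schema = format.lower()
    if schema not in ("newick", "nexus"):
        raise ValidationError(f"unknown tree format {format!r}")
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=tns)
    for t in trees:
        tl.append(dendropy.Tree.get(data=t.to_newick(), schema="newick",
                                    taxon_namespace=tns))
    kwargs = {"real_value_format_specifier": ".17g"}
    if schema == "newick":
        kwargs["suppress_rooting"] = True
    tl.write(path=path, schema=schema, **kwargs)


# -- majority-rule consensus ---------------------------------------------


def _clades_and_lengths(tree: PhyloTree):
    """Map clade (frozenset of tip labels) -> subtending edge length.

    Includes trivial single-tip clades; excludes the root (full tip set).
    """
    out: dict[frozenset, float] = {}
    tipsets: dict[int, frozenset] = {}
    all_tips = frozenset(tree.tip_labels)
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            s = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(tipsets[id(c)] for c in node.child_nodes()))
        tipsets[id(node)] = s
        if node.parent_node is not None and s != all_tips:
            out[s] = node.edge.length if node.edge.length is not None else 0.0
    return out


def majority_consensus(trees: list[PhyloTree],
                       threshold: float = 0.5) -> PhyloTree:
    """Strict majority-rule consensus of a set of trees on identical tips.

    A non-trivial clade enters the consensus iff its frequency strictly
    exceeds ``threshold`` (so exact ties at 50% are excluded). Each
    consensus branch length is the arithmetic mean of that clade's
    subtending edge length over the trees that contain the clade.
    """
    if not trees:
        raise ValidationError("need at least one tree")
    if not (0.5 <= threshold < 1.0):
        raise ValidationError(
            f"threshold must lie in [0.5, 1); got {threshold}")
    ref = set(trees[0].tip_labels)
    for k, t in enumerate(trees[1:], start=2):
        s = set(t.tip_labels)
        if s != ref:
            diff = sorted(ref.symmetric_difference(s))
            raise ValidationError(
                f"tree {k} tip set differs from tree 1; symmetric "
                f"difference: {diff}")

    counts: Counter = Counter()
    length_sums: dict[frozenset, float] = {}
    for t in trees:
        for clade, length in _clades_and_lengths(t).items():
            counts[clade] += 1
            length_sums[clade] = length_sums.get(clade, 0.0) + length

    ntrees = len(trees)
    selected = []
    for clade, k in counts.items():
        if len(clade) == 1:
            continue
        if k > threshold * ntrees:
            selected.append(clade)
    # nest larger clades outside smaller ones; >50% clades never conflict
    selected.sort(key=len, reverse=True)

    tns = dendropy.TaxonNamespace(sorted(ref))
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    clade_node = {frozenset(ref): root}

    def smallest_parent(clade):
        best = frozenset(ref)
        for other in selected:
            if other != clade and clade < other and len(other) < len(best):
                best = other
        return best

    for clade in selected:
        node = dendropy.Node()
        node.edge.length = length_sums[clade] / counts[clade]
        clade_node[clade] = node
    for clade in selected:
        clade_node[smallest_parent(clade)].add_child(clade_node[clade])
    for label in sorted(ref):
        leaf = dendropy.Node(taxon=tns.get_taxon(label))
        c = frozenset([label])
        leaf.edge.length = length_sums[c] / counts[c]
        parent = frozenset(ref)
        for other in selected:
            if label in other and len(other) < len(parent):
                parent = other
        clade_node[parent].add_child(leaf)
    return PhyloTree(tree)
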