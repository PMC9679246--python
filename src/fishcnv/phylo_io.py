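"""Rooted phylogenies: Newick I/O, validation, pruning, and CAFE count extraction.

Trees are the backbone of every downstream step: the species tree supplies
the phylogenetic covariance for the regressions, and CAFE-style gene trees
carry per-species copy counts in their leaf labels.  Parsing is delegated to
dendropy; the in-memory representation here is a minimal rooted node
structure over which depth, pruning and ultrametricity logic is exact and
easy to audit.

Leaf labels are canonicalized (lowercased, spaces mapped to underscores)
because species names arrive from several sources with inconsistent casing
and spacing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "NewickError",
    "TreeValidationError",
    "canonical_name",
    "read_newick",
    "extract_cafe_counts",
    "read_gene_tree_file",
    "write_gene_tree_file",
]


class NewickError(ValueError):
    """Malformed Newick text (unbalanced parentheses, stray tokens, ...)."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a tree invariant."""


def canonical_name(label: str) -> str:
    """Canonical species identifier: stripped, lowercased, spaces -> underscores."""
    return label.strip().lower().replace(" ", "_")


@dataclass
class Node:
    """One node of a rooted tree; ``length`` is the edge to the parent (root: 0)."""

    label: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree with nonnegative branch lengths and unique leaf labels.

    Branch lengths are in time units (e.g. My) for time-calibrated species
    trees; gene trees reuse the same structure.  Zero-length branches are
    permitted (timetree polytomies resolved with zero edges).
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> None:
        labels = [leaf.label for leaf in self.leaves()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeValidationError("every leaf must carry a label")
        seen: dict[str, int] = {}
        for lbl in labels:
            seen[lbl] = seen.get(lbl, 0) + 1
        dups = sorted(l for l, k in seen.items() if k > 1)
        if dups:
            raise TreeValidationError(f"duplicate leaf labels after canonicalization: {dups}")
        for node in self.preorder():
            if node.length < 0:
                raise TreeValidationError(f"negative branch length {node.length} at {node.label or 'internal node'}")

    # -- traversal -----------------------------------------------------------------

    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- geometry ------------------------------------------------------------------

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path length per leaf label."""
        depths: dict[str, float] = {}

        def walk(node: Node, d: float) -> None:
            d += node.length
            if node.is_leaf:
                depths[node.label] = d
            for ch in node.children:
                walk(ch, d)

        walk(self.root, -self.root.length)  # root edge does not contribute
        return depths

    def max_depth(self) -> float:
        return max(self.leaf_depths().values())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        """All root-to-leaf depths equal within ``rtol`` relative tolerance."""
        depths = list(self.leaf_depths().values())
        hi, lo = max(depths), min(depths)
        if hi == 0:
            return lo == 0
        return (hi - lo) <= rtol * hi

    def pairwise_distances(self) -> dict[tuple[str, str], float]:
        """Patristic distance for every unordered leaf pair (keys sorted)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            below: dict[str, float] = {}
            merged: list[dict[str, float]] = []
            for ch in node.children:
                sub = {lbl: d + ch.length for lbl, d in walk(ch).items()}
                for prev in merged:
                    for a, da in prev.items():
                        for b, db in sub.items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
                merged.append(sub)
                below.update(sub)
            return below

        walk(self.root)
        return dists

    # -- manipulation --------------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            return Node(node.label, node.length, [clone(c) for c in node.children])

        return PhyloTree(clone(self.root))

    def prune_to_taxa(self, taxa: Iterable[str]) -> "PhyloTree":
        """Induced subtree on ``taxa``; pairwise leaf path lengths are preserved.

        Non-root unary nodes are collapsed by summing branch lengths.  The
        root is kept in place (it may end up unary), so root-to-leaf depths
        are preserved as well.
        """
        keep = {canonical_name(t) for t in taxa}
        missing = sorted(keep - set(self.leaf_labels))
        if missing:
            raise TreeValidationError(f"taxa absent from the tree: {missing}")
        if len(keep) < 2:
            raise TreeValidationError("pruning requires at least 2 retained taxa")

        def rebuild(node: Node) -> Node | None:
            if node.is_leaf:
                return Node(node.label, node.length) if node.label in keep else None
            kept = [c for c in (rebuild(ch) for ch in node.children) if c is not None]
            if not kept:
                return None
            if len(kept) == 1 and node is not self.root:
                # collapse unary node: child absorbs this edge
                kept[0].length += node.length
                return kept[0]
            return Node(node.label, node.length, kept)

        new_root = rebuild(self.root)
        assert new_root is not None
        return PhyloTree(new_root)

    # -- serialization -------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt_label(lbl: str | None) -> str:
            if not lbl:
                return ""
            if re.search(r"[\s()\[\]:;,']", lbl):
                return "'" + lbl.replace("'", "''") + "'"
            return lbl

        def fmt(node: Node, with_length: bool = True) -> str:
            body = fmt_label(node.label)
            if node.children:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")" + body
            if with_length:
                body += f":{node.length:.12g}"
            return body

        return fmt(self.root, with_length=self.root.length != 0) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.n_leaves()} leaves, depth~{self.max_depth():.3g})"


def _from_dendropy(dnode: dendropy.Node, canonicalize: bool) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    if label is not None and canonicalize:
        label = canonical_name(label)
    length = dnode.edge.length if dnode.edge.length is not None else 0.0
    return Node(label, float(length), [_from_dendropy(c, canonicalize) for c in dnode.child_nodes()])


def read_newick(text: str, canonicalize: bool = True) -> PhyloTree:
    """Parse a single rooted Newick statement into a validated :class:`PhyloTree`.

    Labels may be quoted; missing branch lengths default to 0.  Raises
    :class:`NewickError` on malformed input (the dendropy message carries the
    offending position) and :class:`TreeValidationError` on duplicate leaf
    labels or negative branch lengths.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickError(f"Newick statement must end in ';' (got {stripped[-20:]!r} at offset {len(stripped)})")
    if stripped.count("(") != stripped.count(")"):
        raise NewickError(
            f"unbalanced parentheses: {stripped.count('(')} '(' vs {stripped.count(')')} ')'"
        )
    try:
        # taxa are not interned so duplicate labels reach our own validation,
        # which reports them as a tree-invariant violation rather than a parse error
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    internal_leaves = [n for n in dtree.leaf_node_iter() if n.taxon is None and not n.label]
    if internal_leaves:
        raise NewickError("malformed Newick: unlabeled leaf node")
    return PhyloTree(_from_dendropy(dtree.seed_node, canonicalize))


# ---------------------------------------------------------------------------
# CAFE gene trees: leaf labels end in a copy-count suffix, '<species>_<int>'
# ---------------------------------------------------------------------------

DEFAULT_COUNT_PATTERN = re.compile(r"^(?P<species>.+)_(?P<count>\d+)$")


def extract_cafe_counts(
    gene_tree_text: str,
    count_pattern: re.Pattern | str = DEFAULT_COUNT_PATTERN,
) -> dict[str, int]:
    """Copy counts per species from a CAFE-style gene tree.

    The default dialect encodes counts as a ``_<integer>`` leaf-label suffix,
    e.g. ``danio_rerio_3``.  Species absent from the tree are absent from the
    returned map — distinct from a present species with count 0.  A custom
    regular expression with ``species`` and ``count`` groups overrides the
    dialect.
    """
    if isinstance(count_pattern, str):
        count_pattern = re.compile(count_pattern)
    tree = read_newick(gene_tree_text)
    counts: dict[str, int] = {}
    for label in tree.leaf_labels:
        m = count_pattern.match(label)
        if m is None:
            raise ValueError(f"leaf {label!r} lacks a parseable copy-count suffix")
        counts[canonical_name(m.group("species"))] = int(m.group("count"))
    return counts


def read_gene_tree_file(trees_path, map_path) -> dict[str, str]:
    """Gene symbol -> Newick text, from a one-tree-per-line file plus a sidecar map.

    The sidecar TSV has columns ``line`` (1-based line number) and ``gene``.
    """
    with open(trees_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    mapping: dict[int, str] = {}
    with open(map_path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["line", "gene"]:
            raise ValueError(f"gene map header must be 'line\\tgene', got {header}")
        for ln in fh:
            if not ln.strip():
                continue
            idx, gene = ln.rstrip("\n").split("\t")
            mapping[int(idx)] = gene
    out: dict[str, str] = {}
    for idx, gene in sorted(mapping.items()):
        if not 1 <= idx <= len(lines):
            raise ValueError(f"gene map line {idx} out of range (file has {len(lines)} trees)")
        out[gene] = lines[idx - 1]
    return out


def write_gene_tree_file(gene_trees: Mapping[str, str], trees_path, map_path) -> None:
    """Inverse of :func:`read_gene_tree_file`."""
    genes = list(gene_trees)
    with open(trees_path, "w") as fh:
        for g in genes:
            fh.write(gene_trees[g].strip() + "\n")
    with open(map_path, "w") as fh:
        fh.write("line\tgene\n")
        for i, g in enumerate(genes, start=1):
            fh.write(f"{i}\t{g}\n")
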