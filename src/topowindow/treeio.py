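"""Newick tree I/O and path-length queries.

Thin, well-specified wrappers around :mod:`dendropy` providing the handful of
tree operations the window pipeline needs: parsing and serialising newick
strings, pruning a tree to a focal taxon set (with suppression of the induced
degree-2 nodes, summing branch lengths), outgroup rooting, patristic
distances and MRCA-to-MRCA path lengths.  These mirror the classic
``nw_prune`` / ``nw_reroot`` / ``nw_distance`` command-line utilities.

All functions are non-destructive: the input tree is never modified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "NewickParseError",
    "TaxonSet",
    "WindowTree",
    "parse_newick",
    "serialize_newick",
    "leaf_labels",
    "prune_taxa",
    "reroot",
    "patristic_distance",
    "mrca_node",
    "mrca_path_length",
    "read_tree_file",
    "write_tree_file",
]

Tree = dendropy.Tree


class NewickParseError(ValueError):
    """Malformed newick input; message carries the character position."""


@dataclass(frozen=True)
class TaxonSet:
    """Ordered focal taxon labels with a designated outgroup."""

    labels: tuple[str, ...]
    outgroup: str

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in taxon set")
        if self.outgroup not in self.labels:
            raise ValueError(f"outgroup {self.outgroup!r} not in taxon set")

    @property
    def ingroup(self) -> tuple[str, ...]:
        return tuple(x for x in self.labels if x != self.outgroup)

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.labels


@dataclass
class WindowTree:
    """A genomic window (BED convention, 0-based half-open) plus its tree."""

    chrom: str
    start: int
    end: int
    tree: dendropy.Tree
    flags: set[str] = field(default_factory=set)

    @property
    def span(self) -> int:
        return self.end - self.start


def _check_balanced(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced parentheses at character {pos}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} unclosed at end of statement"
        )


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single newick statement into a tree.

    Raises :class:`NewickParseError` (with a character position where
    determinable) on unbalanced parentheses, duplicate leaf labels or empty
    input.
    """
    if not text or not text.strip():
        raise NewickParseError("empty newick input at character 0")
    _check_balanced(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(str(exc)) from exc
    labels = leaf_labels(tree)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickParseError(f"duplicate leaf labels: {', '.join(dupes)}")
    for node in tree:
        if node.edge.length is not None and node.edge.length < 0:
            raise NewickParseError(
                f"negative branch length on edge above {_edge_name(node)}"
            )
    return tree


def serialize_newick(tree: dendropy.Tree) -> str:
    """One-line newick string, branch lengths at up to 10 significant digits."""
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
        unquoted_underscores=True,
    )
    return out.strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _find_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    node = tree.find_node_with_taxon_label(label)
    if node is None:
        raise KeyError(f"leaf {label!r} not found in tree")
    return node


def prune_taxa(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict a tree to ``keep``, suppressing induced degree-2 nodes.

    Branch lengths across suppressed nodes are summed, as in ``nw_prune``;
    pairwise patristic distances among kept leaves are conserved.
    """
    keep = list(keep)
    present = set(leaf_labels(tree))
    missing = sorted(set(keep) - present)
    if missing:
        raise KeyError(f"labels not in tree: {', '.join(missing)}")
    if len(keep) < 3:
        raise ValueError("need at least 3 taxa to keep")
    out = tree.clone(depth=1)
    out.retain_taxa_with_labels(keep)
    out.purge_taxon_namespace()
    return out


def reroot(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the edge subtending ``outgroup``, splitting its length evenly.

    The unrooted topology and all pairwise patristic distances are unchanged;
    rerooting twice on the same leaf is a topological no-op.
    """
    out = tree.clone(depth=1)
    node = out.find_node_with_taxon_label(outgroup)
    if node is None:
        raise KeyError(f"outgroup {outgroup!r} not found in tree")
    parent = node.parent_node
    if parent is out.seed_node and len(parent.child_nodes()) == 2:
        return out  # already rooted on the outgroup edge
    edge = node.edge
    if edge.length is None:
        out.reroot_at_edge(edge, update_bipartitions=False)
    else:
        half = edge.length / 2.0
        out.reroot_at_edge(
            edge, length1=half, length2=half, update_bipartitions=False
        )
    out.suppress_unifurcations()
    return out


def _edge_name(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    tips = sorted(
        leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon is not None
    )
    return "{" + ",".join(tips) + "}"


def _resolve_node(tree: dendropy.Tree, endpoint) -> dendropy.Node:
    if isinstance(endpoint, dendropy.Node):
        return endpoint
    return _find_leaf(tree, endpoint)


def _path_to_root(node: dendropy.Node) -> list[dendropy.Node]:
    path = [node]
    while path[-1].parent_node is not None:
        path.append(path[-1].parent_node)
    return path


def patristic_distance(tree: dendropy.Tree, a, b) -> float:
    """Sum of branch lengths on the unique path between two nodes or leaves.

    Symmetric; zero for identical endpoints.  Raises ``ValueError`` naming
    the offending edge if a branch length on the path is missing.
    """
    na = _resolve_node(tree, a)
    nb = _resolve_node(tree, b)
    if na is nb:
        return 0.0
    pa = _path_to_root(na)
    pb = _path_to_root(nb)
    in_a = {id(n): i for i, n in enumerate(pa)}
    mrca = None
    for n in pb:
        if id(n) in in_a:
            mrca = n
            break
    if mrca is None:
        raise ValueError("endpoints are not in the same tree")
    total = 0.0
    for side in (pa, pb):
        for n in side:
            if n is mrca:
                break
            if n.edge.length is None:
                raise ValueError(
                    f"missing branch length on edge above {_edge_name(n)}"
                )
            total += n.edge.length
    return total


def mrca_node(tree: dendropy.Tree, labels: Sequence[str]) -> dendropy.Node:
    """Most recent common ancestor node of a non-empty leaf label set."""
    if not labels:
        raise ValueError("empty taxon set has no MRCA")
    nodes = [_find_leaf(tree, lab) for lab in labels]
    paths = [_path_to_root(n) for n in nodes]
    common = set(id(n) for n in paths[0])
    for p in paths[1:]:
        common &= {id(n) for n in p}
    for n in paths[0]:
        if id(n) in common:
            return n
    raise ValueError("no common ancestor found")  # pragma: no cover


def mrca_path_length(
    tree: dendropy.Tree, set_a: Sequence[str], set_b: Sequence[str]
) -> float:
    """Path length from MRCA(set_a) up to MRCA(set_a ∪ set_b).

    Zero when the two MRCA nodes coincide (e.g. nested clades).
    """
    if not set_a or not set_b:
        raise ValueError("both taxon sets must be non-empty")
    inner = mrca_node(tree, list(set_a))
    outer = mrca_node(tree, list(set_a) + list(set_b))
    return patristic_distance(tree, inner, outer)


# ---------------------------------------------------------------------------
# File I/O: one newick per line, optional tab-separated BED side-car index.

def read_tree_file(
    tree_path: str | Path, index_path: str | Path | None = None
) -> list[WindowTree]:
    """Read window trees (one newick per line) with an optional BED index.

    The index file has one ``chrom<TAB>start<TAB>end`` line per tree line
    (0-based half-open).  Without an index, windows get placeholder
    coordinates on a single pseudo-chromosome in input order.
    """
    lines = [
        ln.strip()
        for ln in Path(tree_path).read_text().splitlines()
        if ln.strip()
    ]
    trees = [parse_newick(ln) for ln in lines]
    if index_path is None:
        return [
            WindowTree(chrom="unplaced", start=i, end=i + 1, tree=t)
            for i, t in enumerate(trees)
        ]
    idx_lines = [
        ln.split("\t")
        for ln in Path(index_path).read_text().splitlines()
        if ln.strip()
    ]
    if len(idx_lines) != len(trees):
        raise ValueError(
            f"index has {len(idx_lines)} rows but tree file has "
            f"{len(trees)} trees"
        )
    return [
        WindowTree(chrom=row[0], start=int(row[1]), end=int(row[2]), tree=t)
        for row, t in zip(idx_lines, trees)
    ]


def write_tree_file(
    windows: Sequence[WindowTree],
    tree_path: str | Path,
    index_path: str | Path | None = None,
) -> None:
    with open(tree_path, "w") as fh:
        for w in windows:
            fh.write(serialize_newick(w.tree) + "\n")
    if index_path is not None:
        with open(index_path, "w") as fh:
            for w in windows:
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")
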