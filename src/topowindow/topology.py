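"""Rooted topology catalogues and canonical classification of window trees.

A window tree is reduced to its rooted leaf-labelled topology on a focal
taxon set: prune to the focal taxa, root on the outgroup, strip branch
lengths, and write the shape as a canonical nested string in which every
internal node's children are sorted by the lexicographically smallest leaf
label they subtend.  Two trees receive the same canonical string iff they
have the same rooted topology on the focal set — so the string doubles as a
hashable class identifier.

The module also enumerates every rooted binary topology on a taxon set
(optionally with required clades), which is what makes the six-taxon
15-topology catalogue and the exhaustive coalescent species-tree search
possible.  The number of rooted binary shapes on n free lineages is the
double factorial (2n-3)!!.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .treeio import TaxonSet, leaf_labels

__all__ = [
    "UNRESOLVED",
    "OTHER",
    "TopologyClass",
    "TopologyCatalogue",
    "FrequencyTable",
    "canonical_structure",
    "canonical_string",
    "canonical_id",
    "enumerate_rooted_topologies",
    "tabulate",
]

#: Sentinel aliases for trees outside a catalogue.
UNRESOLVED = "unresolved"
OTHER = "other"


@dataclass(frozen=True)
class TopologyClass:
    canonical: str
    index: int
    alias: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.alias or self.canonical


# ---------------------------------------------------------------------------
# Canonicalisation

def _induce(node: dendropy.Node, focal: frozenset):
    """Topology induced on ``focal`` below ``node``; single-child chains
    collapsed.  Returns a leaf label, a tuple of substructures, or None."""
    if node.is_leaf():
        lab = node.taxon.label if node.taxon is not None else None
        return lab if lab in focal else None
    kids = []
    for child in node.child_nodes():
        sub = _induce(child, focal)
        if sub is not None:
            kids.append(sub)
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return tuple(kids)


def _nested_to_adjacency(nested):
    """Unrooted adjacency map for an induced structure.  Internal nodes get
    integer ids, leaves keep their labels; a degree-2 root is suppressed."""
    adj: dict = {}
    counter = itertools.count()

    def build(x):
        if isinstance(x, str):
            adj.setdefault(x, [])
            return x
        nid = next(counter)
        adj[nid] = []
        for c in x:
            cid = build(c)
            adj[nid].append(cid)
            adj[cid].append(nid)
        return nid

    root = build(nested)
    if not isinstance(root, str) and len(adj[root]) == 2:
        a, b = adj[root]
        adj[a] = [x for x in adj[a] if x != root] + [b]
        adj[b] = [x for x in adj[b] if x != root] + [a]
        del adj[root]
    return adj


def _root_at(adj, outgroup: str):
    """Rooted nested structure: root children are the outgroup and the rest."""
    (anchor,) = adj[outgroup]

    def subtree(node, parent):
        if isinstance(node, str):
            return node
        return tuple(subtree(n, node) for n in adj[node] if n != parent)

    return (outgroup, subtree(anchor, outgroup))


def _sort_nested(x):
    if isinstance(x, str):
        return x, x
    ranked = sorted(_sort_nested(c) for c in x)
    key = ranked[0][0]
    return key, tuple(r[1] for r in ranked)


def _nested_str(x) -> str:
    if isinstance(x, str):
        return x
    return "(" + ",".join(_nested_str(c) for c in x) + ")"


def _is_binary(x) -> bool:
    if isinstance(x, str):
        return True
    return len(x) == 2 and all(_is_binary(c) for c in x)


def canonical_structure(tree: dendropy.Tree, focal: TaxonSet):
    """Canonical rooted nested-tuple topology of ``tree`` on ``focal``.

    Prunes to the focal taxa (implicitly, without copying the tree), roots on
    the focal outgroup, strips branch lengths, and sorts children by smallest
    subtended leaf label.
    """
    present = set(leaf_labels(tree))
    missing = sorted(set(focal.labels) - present)
    if missing:
        raise KeyError(f"focal taxa not in tree: {', '.join(missing)}")
    nested = _induce(tree.seed_node, frozenset(focal.labels))
    adj = _nested_to_adjacency(nested)
    rooted = _root_at(adj, focal.outgroup)
    _, sorted_nested = _sort_nested(rooted)
    return sorted_nested


def canonical_string(tree: dendropy.Tree, focal: TaxonSet) -> str:
    return _nested_str(canonical_structure(tree, focal))


# ---------------------------------------------------------------------------
# Enumeration

def _rooted_shapes(leaves: Sequence[str]):
    """All rooted binary shapes on ``leaves`` (nested tuples), each once.

    Built by stepwise leaf insertion: a shape on k leaves has 2k-2 insertion
    points plus one above the root, giving the (2n-3)!! recurrence.
    """
    if len(leaves) == 1:
        yield leaves[0]
        return

    def insert_everywhere(shape, leaf):
        # new root above the old one
        yield (shape, leaf)
        if not isinstance(shape, str):
            a, b = shape
            for sub in insert_everywhere(a, leaf):
                yield (sub, b)
            for sub in insert_everywhere(b, leaf):
                yield (a, sub)

    for shape in _rooted_shapes(leaves[:-1]):
        yield from insert_everywhere(shape, leaves[-1])


def _leafset(x) -> frozenset:
    if isinstance(x, str):
        return frozenset([x])
    out = frozenset()
    for c in x:
        out |= _leafset(c)
    return out


def enumerate_rooted_topologies(
    taxa: TaxonSet,
    constraints: Sequence[Iterable[str]] = (),
    aliases: Mapping[str, str] | None = None,
) -> list[TopologyClass]:
    """Every rooted binary topology on ``taxa`` containing all required clades.

    The outgroup is fixed as one child of the root; ``constraints`` are
    leaf subsets of the ingroup that must each form a clade.  Constrained
    clades are enumerated as units and expanded by their own rooted shapes,
    so the class count is the product of double factorials.  Classes are
    indexed in sorted canonical-string order; ``aliases`` maps alias names to
    canonical strings.
    """
    ingroup = list(taxa.ingroup)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    cons = [frozenset(c) for c in constraints]
    all_in = set(ingroup)
    for c in cons:
        if not c <= all_in:
            raise ValueError(f"constraint {sorted(c)} is not an ingroup subset")
    for a, b in itertools.combinations(cons, 2):
        if a & b and not (a <= b or b <= a):
            raise ValueError(
                f"incompatible constraints: {sorted(a)} and {sorted(b)}"
            )
        if a & b:
            raise ValueError("nested constraints are not supported")

    # collapse each constrained clade to a meta-leaf
    meta_names = {}
    meta_leaves = []
    covered: set[str] = set()
    for i, c in enumerate(cons):
        name = f"__meta{i}__"
        meta_names[name] = sorted(c)
        meta_leaves.append(name)
        covered |= set(c)
    free = [x for x in ingroup if x not in covered]
    skeleton_leaves = sorted(free) + meta_leaves

    sub_shapes = {
        name: list(_rooted_shapes(sorted(members)))
        for name, members in meta_names.items()
    }

    def expand(shape, assignment):
        if isinstance(shape, str):
            return assignment.get(shape, shape)
        return tuple(expand(c, assignment) for c in shape)

    seen: dict[str, tuple] = {}
    for skel in _rooted_shapes(skeleton_leaves):
        for combo in itertools.product(
            *(sub_shapes[m] for m in meta_leaves)
        ):
            assignment = dict(zip(meta_leaves, combo))
            full = (taxa.outgroup, expand(skel, assignment))
            _, nested = _sort_nested(full)
            seen[_nested_str(nested)] = nested

    alias_of: dict[str, str] = {}
    if aliases:
        for alias, canon in aliases.items():  # first binding wins
            alias_of.setdefault(canon, alias)
    classes = [
        TopologyClass(canonical=s, index=i, alias=alias_of.get(s))
        for i, s in enumerate(sorted(seen))
    ]
    return classes


# ---------------------------------------------------------------------------
# Classification against a catalogue

@dataclass
class TopologyCatalogue:
    """Enumerated classes for a focal system, with alias bindings.

    ``classify`` maps any tree to a member class, or to the sentinel classes
    ``other`` (resolved topology outside the catalogue, e.g. one that splits
    a constrained clade) and ``unresolved`` (multifurcating after pruning).
    """

    taxa: TaxonSet
    classes: list[TopologyClass]
    other_class: TopologyClass = field(init=False)
    unresolved_class: TopologyClass = field(init=False)

    def __post_init__(self) -> None:
        self._by_canonical = {c.canonical: c for c in self.classes}
        self._by_alias = {c.alias: c for c in self.classes if c.alias}
        self.other_class = TopologyClass(canonical=OTHER, index=-1, alias=OTHER)
        self.unresolved_class = TopologyClass(
            canonical=UNRESOLVED, index=-2, alias=UNRESOLVED
        )

    @classmethod
    def build(
        cls,
        taxa: TaxonSet,
        constraints: Sequence[Iterable[str]] = (),
        aliases: Mapping[str, str] | None = None,
    ) -> "TopologyCatalogue":
        return cls(
            taxa=taxa,
            classes=enumerate_rooted_topologies(taxa, constraints, aliases),
        )

    def __len__(self) -> int:
        return len(self.classes)

    def by_alias(self, alias: str) -> TopologyClass:
        return self._by_alias[alias]

    def classify(self, tree: dendropy.Tree) -> TopologyClass:
        nested = canonical_structure(tree, self.taxa)
        if not _is_binary(nested):
            return self.unresolved_class
        return self._by_canonical.get(_nested_str(nested), self.other_class)


def canonical_id(
    tree: dendropy.Tree, focal: TaxonSet, catalogue: TopologyCatalogue | None = None
) -> TopologyClass:
    """Canonicalise one tree; without a catalogue an ad-hoc class is returned
    (index -1 unless the shape is unresolved)."""
    if catalogue is not None:
        return catalogue.classify(tree)
    nested = canonical_structure(tree, focal)
    if not _is_binary(nested):
        return TopologyClass(canonical=UNRESOLVED, index=-2, alias=UNRESOLVED)
    return TopologyClass(canonical=_nested_str(nested), index=-1)


# ---------------------------------------------------------------------------
# Frequencies

@dataclass
class FrequencyTable:
    counts: dict[str, int]
    total: int
    label: str | None = None

    @property
    def frequencies(self) -> dict[str, float]:
        return {k: v / self.total for k, v in self.counts.items()}

    def to_rows(self):
        return [
            (k, v, v / self.total)
            for k, v in sorted(self.counts.items(), key=lambda kv: -kv[1])
        ]


def tabulate(
    classes: Sequence[TopologyClass], label: str | None = None
) -> FrequencyTable:
    """Count topology classes; frequencies over the observed windows sum to 1."""
    if not classes:
        raise ValueError("empty class list")
    counts: dict[str, int] = {}
    for c in classes:
        key = c.alias or c.canonical
        counts[key] = counts.get(key, 0) + 1
    return FrequencyTable(counts=counts, total=len(classes), label=label)
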