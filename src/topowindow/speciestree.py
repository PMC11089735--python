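"""Exhaustive coalescent species-tree estimation by rooted-triplet scoring.

For small focal systems the coalescent species tree can be found exactly:
enumerate every rooted topology, score each by the number of rooted leaf
triplets it shares with the input gene trees, and return the argmax.  Under
the multispecies coalescent without gene flow the most probable rooted
triplet matches the species tree for every triple, so the maximiser is a
statistically consistent estimator — the same principle behind
quartet/triplet-based summary methods, made exhaustive because the taxon
set is tiny.  Under strong introgression the estimator can prefer the
introgression topology, a caveat the simulator makes reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

import dendropy

from .treeio import TaxonSet, leaf_labels
from .topology import (
    TopologyClass,
    enumerate_rooted_topologies,
    canonical_structure,
    _nested_str,
)

__all__ = ["TripletScore", "triplet_score", "exhaustive_species_tree"]


@dataclass(frozen=True)
class TripletScore:
    candidate: TopologyClass
    matched: int
    possible: int

    @property
    def normalised(self) -> float:
        return self.matched / self.possible if self.possible else 0.0


def _triplet_cherry(nested, triple: frozenset) -> frozenset | None:
    """The cherry pair of ``triple`` in a rooted nested structure, or None
    if the triple is unresolved (multifurcation)."""

    def leafset(x):
        if isinstance(x, str):
            return frozenset([x]) if x in triple else frozenset()
        out = frozenset()
        for c in x:
            out |= leafset(c)
        return out

    def walk(x):
        # returns cherry if decided within this subtree
        if isinstance(x, str):
            return None
        subs = [(c, leafset(c)) for c in x]
        for c, ls in subs:
            if len(ls) == 3:
                return walk(c)
        twos = [ls for _, ls in subs if len(ls) == 2]
        if len(twos) == 1:
            # check the pair resolves deeper: the pair may still be split
            for c, ls in subs:
                if len(ls) == 2:
                    deeper = walk(c)
                    return deeper if deeper is not None else ls
        return None

    return walk(nested)


def _tree_triplets(
    tree: dendropy.Tree, taxa: TaxonSet
) -> dict[frozenset, frozenset | None]:
    nested = canonical_structure(tree, taxa)
    out = {}
    for triple in combinations(taxa.ingroup, 3):
        fs = frozenset(triple)
        out[fs] = _triplet_cherry(nested, fs)
    return out


def _candidate_triplets(
    candidate: TopologyClass, taxa: TaxonSet
) -> dict[frozenset, frozenset | None]:
    from .treeio import parse_newick

    tree = parse_newick(candidate.canonical + ";")
    return _tree_triplets(tree, taxa)


def triplet_score(
    candidate: TopologyClass,
    gene_trees: Sequence[dendropy.Tree],
    taxa: TaxonSet,
) -> TripletScore:
    """Matched rooted triplets between a candidate topology and gene trees.

    Every gene tree must contain the focal taxa and be rootable on the
    focal outgroup (an ingroup-only tree is rejected).
    """
    cand = _candidate_triplets(candidate, taxa)
    n_triples = len(cand)
    matched = 0
    for gt in gene_trees:
        if taxa.outgroup not in set(leaf_labels(gt)):
            raise ValueError(
                f"gene tree lacks the outgroup {taxa.outgroup!r}; "
                "cannot extract rooted triplets"
            )
        got = _tree_triplets(gt, taxa)
        for triple, cherry in cand.items():
            if cherry is not None and got[triple] == cherry:
                matched += 1
    return TripletScore(
        candidate=candidate, matched=matched,
        possible=len(gene_trees) * n_triples,
    )


def exhaustive_species_tree(
    gene_trees: Sequence[dendropy.Tree],
    taxa: TaxonSet,
    constraints: Sequence[Iterable[str]] = (),
) -> tuple[TopologyClass, pd.DataFrame]:
    """Argmax-triplet-score topology over the full rooted catalogue.

    Returns the winning class and the complete score table (ties broken by
    lexicographic canonical string, which the sorted enumeration makes
    deterministic).
    """
    if not gene_trees:
        raise ValueError("empty gene tree list")
    if len(taxa.ingroup) > 8:
        raise ValueError("exhaustive search is limited to small taxon sets")
    candidates = enumerate_rooted_topologies(taxa, constraints)
    # score all candidates from one triplet tally over the gene trees
    tallies: dict[frozenset, dict[frozenset, int]] = {
        frozenset(t): {} for t in combinations(taxa.ingroup, 3)
    }
    for gt in gene_trees:
        if taxa.outgroup not in set(leaf_labels(gt)):
            raise ValueError(
                f"gene tree lacks the outgroup {taxa.outgroup!r}; "
                "cannot extract rooted triplets"
            )
        for triple, cherry in _tree_triplets(gt, taxa).items():
            if cherry is not None:
                tallies[triple][cherry] = tallies[triple].get(cherry, 0) + 1
    rows = []
    best = None
    for cand in candidates:
        cand_trip = _candidate_triplets(cand, taxa)
        matched = sum(
            tallies[triple].get(cherry, 0)
            for triple, cherry in cand_trip.items()
            if cherry is not None
        )
        score = TripletScore(
            candidate=cand, matched=matched,
            possible=len(gene_trees) * len(cand_trip),
        )
        rows.append({
            "canonical": cand.canonical,
            "alias": cand.alias,
            "matched": score.matched,
            "normalised": score.normalised,
        })
        if best is None or score.matched > best.matched:
            best = score
    table = pd.DataFrame(rows).sort_values(
        ["matched", "canonical"], ascending=[False, True]
    ).reset_index(drop=True)
    return best.candidate, table
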