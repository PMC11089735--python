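"""Alignment windows: splitting, quality filters, 4D sites and NJ trees.

The window pipeline takes a reference-anchored multi-species alignment,
tiles it into fixed-size windows, applies three quality filters (gap ratio,
per-sequence base-composition chi-square homogeneity, and a long-branch
screen on the inferred trees), extracts fourfold-degenerate third codon
positions from coding alignments, and infers a tree per window by
neighbor-joining on Jukes–Cantor distances so the pipeline closes without
external maximum-likelihood software.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from . import treeio

__all__ = [
    "AlignmentWindow",
    "FilterReport",
    "GAP_CHARS",
    "FOURFOLD_PREFIXES",
    "split_windows",
    "filter_report",
    "gap_filter",
    "composition_test",
    "extract_4d_sites",
    "strip_gap_columns",
    "jc_distance_matrix",
    "nj_tree",
    "long_branch_filter",
    "read_window_fastas",
]

GAP_CHARS = frozenset("-")
MISSING_CHARS = frozenset("-N")

#: Codon prefixes whose third position is fourfold degenerate (standard code).
FOURFOLD_PREFIXES = frozenset(
    {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"}
)


@dataclass
class AlignmentWindow:
    """A window of a multi-species alignment on reference coordinates.

    ``chrom`` is None for non-genomic concatenations (4D sites, gap-stripped
    alignments).  All sequences must have equal length.
    """

    chrom: str | None
    start: int
    end: int
    seqs: dict[str, str]
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences differ in length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    @property
    def taxa(self) -> list[str]:
        return list(self.seqs)

    def matrix(self) -> np.ndarray:
        """(taxa x columns) byte matrix, taxa in insertion order."""
        return np.array(
            [np.frombuffer(s.encode("ascii"), dtype="S1") for s in self.seqs.values()]
        )

    @property
    def informative_columns(self) -> int:
        if not self.seqs:
            return 0
        m = self.matrix()
        ok = ~(np.isin(m, [b"-", b"N"]))
        return int((ok.sum(axis=0) >= 2).sum())


@dataclass
class FilterReport:
    window_id: str
    gap_ratio: float
    gap_pass: bool
    composition_stats: dict[str, float]
    composition_pass: dict[str, bool]
    long_branch_flag: bool = False

    @property
    def composition_window_pass(self) -> bool:
        return all(self.composition_pass.values())


def filter_report(
    w: AlignmentWindow,
    max_gap: float = 0.10,
    alpha: float = 0.05,
    long_branch_flag: bool = False,
) -> FilterReport:
    """Assemble the per-window quality report (gap + composition filters)."""
    ok_gap, ratio = gap_filter(w, threshold=max_gap)
    stats_, passed = composition_test(w, alpha=alpha)
    return FilterReport(
        window_id=f"{w.chrom}:{w.start}-{w.end}",
        gap_ratio=ratio,
        gap_pass=ok_gap,
        composition_stats=stats_,
        composition_pass=passed,
        long_branch_flag=long_branch_flag,
    )


def split_windows(
    aln: Mapping[str, str],
    size: int,
    min_informative: int = 30,
    chrom: str = "chr",
) -> list[AlignmentWindow]:
    """Tile an equal-length alignment into consecutive half-open windows.

    Windows whose informative-column count (columns with >= 2 non-gap,
    non-N characters) falls below ``min_informative`` are dropped; the final
    partial window is kept if any columns remain.  With
    ``min_informative=0`` the returned windows tile the input exactly.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if not aln:
        return []
    total = len(next(iter(aln.values())))
    if any(len(s) != total for s in aln.values()):
        raise ValueError("aligned sequences differ in length")
    out = []
    for start in range(0, total, size):
        end = min(start + size, total)
        w = AlignmentWindow(
            chrom=chrom,
            start=start,
            end=end,
            seqs={t: s[start:end] for t, s in aln.items()},
        )
        if w.informative_columns >= min_informative:
            out.append(w)
    return out


def gap_filter(
    w: AlignmentWindow, threshold: float = 0.10
) -> tuple[bool, float]:
    """Fail iff the gap fraction over all characters exceeds ``threshold``
    strictly.  Returns (passed, gap_ratio)."""
    m = w.matrix()
    if m.size == 0:
        return True, 0.0
    ratio = float((m == b"-").sum() / m.size)
    return ratio <= threshold, ratio


def composition_test(
    w: AlignmentWindow, alpha: float = 0.05
) -> tuple[dict[str, float], dict[str, bool]]:
    """Per-sequence base-composition homogeneity chi-square test.

    For each taxon, X^2 = sum_b (o_b - e_b)^2 / e_b over b in {A,C,G,T},
    with e_b = (taxon's ungapped length) x (pooled base frequency over the
    whole alignment, the tested sequence included).  A sequence fails when
    the df=3 p-value is below ``alpha``.  Pooled frequencies are floored at
    1e-6 to keep e_b positive.
    """
    m = w.matrix()
    bases = np.frombuffer(b"ACGT", dtype="S1")
    pooled = np.array([(m == b).sum() for b in bases], dtype=float)
    if pooled.sum() == 0:
        raise ValueError("alignment contains no unambiguous bases")
    freqs = np.maximum(pooled / pooled.sum(), 1e-6)
    freqs = freqs / freqs.sum()
    statistics: dict[str, float] = {}
    passed: dict[str, bool] = {}
    crit = stats.chi2.ppf(1 - alpha, df=3)
    for row, taxon in zip(m, w.taxa):
        obs = np.array([(row == b).sum() for b in bases], dtype=float)
        n = obs.sum()
        if n == 0:
            statistics[taxon] = 0.0
            passed[taxon] = True
            continue
        exp = np.maximum(n * freqs, 1e-6 * n)
        x2 = float(((obs - exp) ** 2 / exp).sum())
        statistics[taxon] = x2
        passed[taxon] = x2 <= crit
    return statistics, passed


def extract_4d_sites(w: AlignmentWindow, frame: int = 0) -> AlignmentWindow:
    """Concatenated fourfold-degenerate third codon positions.

    A codon column is emitted (third position only) when positions 1-2 are
    ungapped, identical across all taxa, and form a fourfold-degenerate
    prefix of the standard genetic code.  Output coordinates are marked
    non-genomic (chrom None).
    """
    if frame is None:
        raise ValueError("codon frame annotation is required")
    m = w.matrix()
    if m.size == 0:
        return AlignmentWindow(chrom=None, start=0, end=0, seqs={})
    n_taxa, n_cols = m.shape
    usable = n_cols - frame
    n_codons = usable // 3
    keep: list[int] = []
    for k in range(n_codons):
        i = frame + 3 * k
        p1 = m[:, i]
        p2 = m[:, i + 1]
        if len(set(p1)) != 1 or len(set(p2)) != 1:
            continue
        prefix = (p1[0] + p2[0]).decode("ascii").upper()
        if any(ch in "-N" for ch in prefix):
            continue
        if prefix in FOURFOLD_PREFIXES:
            keep.append(i + 2)
    seqs = {t: "".join(w.seqs[t][j] for j in keep) for t in w.taxa}
    out = AlignmentWindow(chrom=None, start=0, end=len(keep), seqs=seqs)
    out.flags.add("4d-concatenation")
    return out


def strip_gap_columns(w: AlignmentWindow) -> AlignmentWindow:
    """Drop every column containing a gap or N; output is non-genomic."""
    m = w.matrix()
    if m.size == 0:
        return AlignmentWindow(chrom=None, start=0, end=0, seqs=dict(w.seqs))
    keep = ~np.isin(m, [b"-", b"N"]).any(axis=0)
    seqs = {
        t: m[i, keep].tobytes().decode("ascii")
        for i, t in enumerate(w.taxa)
    }
    out = AlignmentWindow(chrom=None, start=0, end=int(keep.sum()), seqs=seqs)
    out.flags.add("gap-stripped")
    return out


def jc_distance_matrix(
    w: AlignmentWindow, max_distance: float = 5.0
) -> tuple[np.ndarray, list[str], bool]:
    """Jukes–Cantor distances on pairwise-complete columns.

    d = -(3/4) ln(1 - (4/3) p) with p the mismatch fraction over columns
    where both sequences are unambiguous bases.  Saturated pairs
    (p >= 3/4) get ``max_distance`` and the saturation flag is set.
    """
    m = w.matrix()
    taxa = w.taxa
    ok = ~np.isin(m, [b"-", b"N"])
    n = len(taxa)
    d = np.zeros((n, n))
    saturated = False
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            n_shared = int(both.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no shared ungapped columns between {taxa[i]!r} "
                    f"and {taxa[j]!r}"
                )
            p = float((m[i, both] != m[j, both]).sum() / n_shared)
            if p >= 0.75:
                d[i, j] = d[j, i] = max_distance
                saturated = True
            else:
                d[i, j] = d[j, i] = -0.75 * np.log1p(-4.0 * p / 3.0)
    return d, taxa, saturated


def nj_tree(
    w: AlignmentWindow, max_distance: float = 5.0
) -> treeio.Tree:
    """Neighbor-joining tree on JC distances (negative branches clamped).

    Saturated distance pairs mark the window with a ``saturated`` flag.
    """
    if len(w.taxa) < 4:
        raise ValueError("neighbor-joining needs at least 4 taxa")
    d, taxa, saturated = jc_distance_matrix(w, max_distance=max_distance)
    if saturated:
        w.flags.add("saturated")
        warnings.warn(
            f"saturated JC distance capped at {max_distance} in window "
            f"{w.chrom}:{w.start}-{w.end}",
            stacklevel=2,
        )
    dm = DistanceMatrix(d, ids=taxa)
    sk_tree = _skbio_nj(dm, neg_as_zero=True)
    buf = io.StringIO()
    sk_tree.write(buf, format="newick")
    tree = treeio.parse_newick(buf.getvalue().strip())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:  # pragma: no cover
            edge.length = 0.0
    return tree


def long_branch_filter(
    trees: Sequence[treeio.Tree], factor: float = 5.0, min_trees: int = 20
) -> list[bool]:
    """Flag trees in which any taxon's root-to-tip length exceeds ``factor``
    times that taxon's median root-to-tip across all trees.

    A simplified long-branch screen in the spirit of outlier-branch
    trimming tools; with fewer than ``min_trees`` trees no baseline is
    trusted and nothing is flagged (a warning is emitted).
    """
    n = len(trees)
    if n < min_trees:
        warnings.warn(
            f"only {n} trees (< {min_trees}); long-branch filter passes all",
            stacklevel=2,
        )
        return [False] * n
    rtt: dict[str, list[float]] = {}
    per_tree: list[dict[str, float]] = []
    for t in trees:
        depths = {}
        for leaf in t.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
            rtt.setdefault(leaf.taxon.label, []).append(d)
        per_tree.append(depths)
    medians = {lab: float(np.median(v)) for lab, v in rtt.items()}
    flags = []
    for depths in per_tree:
        bad = any(
            medians[lab] > 0 and d > factor * medians[lab]
            for lab, d in depths.items()
        )
        flags.append(bad)
    return flags


def read_window_fastas(paths: Iterable[str | Path]) -> list[AlignmentWindow]:
    """Read per-window multi-FASTA files named ``<chrom>:<start>-<end>``
    (BED half-open coordinates encoded in the stem)."""
    from Bio import SeqIO

    out = []
    for p in paths:
        p = Path(p)
        stem = p.stem
        chrom, _, span = stem.rpartition(":")
        start_s, _, end_s = span.partition("-")
        if not chrom or not start_s or not end_s:
            raise ValueError(
                f"cannot parse coordinates from filename {p.name!r} "
                "(expected <chrom>:<start>-<end>)"
            )
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(p), "fasta")
        }
        out.append(
            AlignmentWindow(
                chrom=chrom, start=int(start_s), end=int(end_s), seqs=seqs
            )
        )
    return out
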