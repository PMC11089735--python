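"""Introgression inference: D-statistic, block permutation test, region calls.

Three complementary lines of evidence, all consuming the window-tree layer:

* the ABBA-BABA D-statistic ``D = (sum ABBA - sum BABA)/(sum ABBA + sum
  BABA)`` with a weighted delete-one block jackknife standard error (the
  block totals weight each leave-one-out replicate), giving ``Z = D/SE``;
* a block permutation test comparing a distance statistic averaged over an
  observed window set against the same statistic over randomly placed
  contiguous blocks of background windows — the null preserves linkage by
  sampling blocks, not windows;
* a region caller combining run length with genome-wide distance
  percentiles: introgressed regions are long runs of the introgression
  topology whose mean recipient-donor distance sits in the extreme low
  tail, resistant regions the converse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import treeio
from .runscan import Run

__all__ = [
    "DStatResult",
    "RegionCall",
    "d_statistic",
    "patterns_from_genotype_matrix",
    "permutation_test",
    "distance_track",
    "call_regions",
    "overlap_genes",
    "read_gene_intervals",
]


@dataclass(frozen=True)
class DStatResult:
    D: float
    SE: float
    Z: float
    n_blocks: int
    n_abba: int
    n_baba: int


def _d(abba: float, baba: float) -> float:
    return (abba - baba) / (abba + baba)


def d_statistic(blocks: pd.DataFrame) -> DStatResult:
    """ABBA-BABA D with weighted delete-one-block jackknife SE.

    ``blocks`` needs columns n_abba and n_baba (one row per genomic block).
    Blocks with zero pattern totals carry no information and are dropped
    from the jackknife.  The weighted jackknife (block weight = its pattern
    total) follows the standard unequal-block-size construction used for
    genomic D statistics.
    """
    abba = np.asarray(blocks["n_abba"], dtype=float)
    baba = np.asarray(blocks["n_baba"], dtype=float)
    if (abba < 0).any() or (baba < 0).any():
        raise ValueError("pattern counts must be non-negative")
    tot_a, tot_b = abba.sum(), baba.sum()
    if tot_a + tot_b == 0:
        raise ValueError("all-zero pattern counts: D is undefined")
    d_hat = _d(tot_a, tot_b)
    m = abba + baba
    keep = m > 0
    abba, baba, m = abba[keep], baba[keep], m[keep]
    n_blocks = int(keep.sum())
    if n_blocks < 2:
        raise ValueError("need >= 2 non-empty blocks for a jackknife SE")
    n = m.sum()
    loo = (tot_a - abba + tot_b - baba)
    d_loo = ((tot_a - abba) - (tot_b - baba)) / loo
    h = n / m
    # Busing et al. (1999) delete-m_j jackknife variance
    theta_j = n_blocks * d_hat - ((1.0 - m / n) * d_loo).sum()
    tau = h * d_hat - (h - 1.0) * d_loo
    var = float((((tau - theta_j) ** 2) / (h - 1.0)).sum() / n_blocks)
    se = float(np.sqrt(var))
    if se > 0:
        z = d_hat / se
    else:
        z = 0.0 if d_hat == 0 else float(np.inf) * (1 if d_hat > 0 else -1)
    return DStatResult(
        D=float(d_hat), SE=se, Z=float(z), n_blocks=n_blocks,
        n_abba=int(tot_a), n_baba=int(tot_b),
    )


def patterns_from_genotype_matrix(
    geno: np.ndarray,
    positions: np.ndarray,
    chroms: Sequence[str],
    quartet_order: tuple[int, int, int, int] = (0, 1, 2, 3),
    block: int = 5_000_000,
) -> pd.DataFrame:
    """ABBA/BABA block counts from a biallelic genotype matrix.

    ``geno`` is (sites x taxa) of 0/1 allele codes; the outgroup column
    (last of ``quartet_order``) defines the ancestral state per site.
    Returns the same block table ``d_statistic`` consumes.
    """
    geno = np.asarray(geno)
    i1, i2, i3, io = quartet_order
    anc = geno[:, io]
    der1 = geno[:, i1] != anc
    der2 = geno[:, i2] != anc
    der3 = geno[:, i3] != anc
    abba = ~der1 & der2 & der3
    baba = der1 & ~der2 & der3
    rows: dict[tuple[str, int], list[int]] = {}
    for k in range(len(geno)):
        key = (chroms[k], int(positions[k] // block) * block)
        acc = rows.setdefault(key, [0, 0])
        acc[0] += int(abba[k])
        acc[1] += int(baba[k])
    data = [
        (c, s, s + block, ab[0], ab[1])
        for (c, s), ab in sorted(rows.items())
    ]
    return pd.DataFrame(
        data, columns=["chrom", "start", "end", "n_abba", "n_baba"]
    )


# ---------------------------------------------------------------------------
# Permutation test

def permutation_test(
    observed_values: np.ndarray,
    background_values: np.ndarray,
    block: int = 295,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> tuple[float, np.ndarray]:
    """Empirical p-value for a mean statistic against contiguous-block nulls.

    The observed statistic is ``mean(observed_values)``; each null draw is
    the mean of a uniformly placed contiguous block of ``block`` background
    values.  The add-one estimator ``p = (1 + #{null >= obs}) / (1 +
    n_perm)`` keeps p strictly positive.  ``alternative`` is ``greater``
    (distance increased), ``less``, or ``two-sided``.

    Returns (p, null_distribution).
    """
    observed_values = np.asarray(observed_values, dtype=float)
    background_values = np.asarray(background_values, dtype=float)
    if observed_values.size == 0:
        raise ValueError("empty observed window set")
    if block > background_values.size:
        raise ValueError(
            f"block size {block} exceeds background size "
            f"{background_values.size}"
        )
    if rng is None:
        rng = np.random.default_rng()
    obs = float(observed_values.mean())
    csum = np.concatenate([[0.0], np.cumsum(background_values)])
    starts = rng.integers(0, background_values.size - block + 1, size=n_perm)
    null = (csum[starts + block] - csum[starts]) / block
    p_greater = (1.0 + (null >= obs).sum()) / (1.0 + n_perm)
    p_less = (1.0 + (null <= obs).sum()) / (1.0 + n_perm)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(p), null


def distance_track(
    window_trees: Sequence[treeio.WindowTree],
    pair_a: Sequence[str],
    pair_b: Sequence[str],
    kind: str = "patristic",
) -> np.ndarray:
    """Per-window distances between two leaf sets.

    ``patristic``: mean leaf-to-leaf patristic distance over the product of
    the two sets (e.g. recipient vs each donor).  ``mrca``: path length
    from MRCA(pair_a) to MRCA(pair_a + pair_b).
    """
    out = np.empty(len(window_trees))
    for i, wt in enumerate(window_trees):
        if kind == "patristic":
            vals = [
                treeio.patristic_distance(wt.tree, a, b)
                for a in pair_a for b in pair_b
            ]
            out[i] = float(np.mean(vals))
        elif kind == "mrca":
            out[i] = treeio.mrca_path_length(wt.tree, pair_a, pair_b)
        else:
            raise ValueError(f"unknown distance kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# Region calling

@dataclass(frozen=True)
class RegionCall:
    chrom: str
    start: int
    end: int
    kind: str  # "introgressed" | "resistant"
    run_length: int
    mean_distance: float
    percentile_rank: float


def call_regions(
    track: np.ndarray,
    runs: Sequence[Run],
    intro_class: str,
    resist_class: str,
    intro_pct: float = 0.01,
    intro_minrun: int = 10,
    resist_pct: float = 0.01,
    resist_minrun: int = 5,
) -> list[RegionCall]:
    """Introgressed and resistant region calls.

    ``track`` holds one distance per retained window (same ordering the
    runs were detected on).  An introgressed call is a run of
    ``intro_class`` strictly longer than ``intro_minrun`` whose mean
    distance falls strictly below the genome-wide ``intro_pct`` quantile of
    per-window distances; a resistant call is a run of ``resist_class``
    strictly longer than ``resist_minrun`` with mean strictly above the
    ``1 - resist_pct`` quantile.
    """
    track = np.asarray(track, dtype=float)
    if track.size == 0:
        raise ValueError("empty distance track: quantiles undefined")
    q_lo = float(np.quantile(track, intro_pct))
    q_hi = float(np.quantile(track, 1.0 - resist_pct))
    sorted_track = np.sort(track)
    calls: list[RegionCall] = []
    for r in runs:
        vals = track[r.start_ordinal : r.start_ordinal + r.length]
        mean = float(vals.mean())
        rank = float(np.searchsorted(sorted_track, mean, side="right")
                     / track.size)
        if (
            r.class_key == intro_class
            and r.length > intro_minrun
            and mean < q_lo
        ):
            calls.append(RegionCall(
                chrom=r.chrom, start=r.start, end=r.end,
                kind="introgressed", run_length=r.length,
                mean_distance=mean, percentile_rank=rank,
            ))
        elif (
            r.class_key == resist_class
            and r.length > resist_minrun
            and mean > q_hi
        ):
            calls.append(RegionCall(
                chrom=r.chrom, start=r.start, end=r.end,
                kind="resistant", run_length=r.length,
                mean_distance=mean, percentile_rank=rank,
            ))
    return calls


# ---------------------------------------------------------------------------
# Gene overlap

def overlap_genes(
    regions: Sequence[RegionCall], genes: pd.DataFrame
) -> pd.DataFrame:
    """Genes overlapping each region by >= 1 bp (half-open intervals).

    ``genes`` needs columns chrom, start, end, name.  Returns one row per
    (region, gene) overlap; genes are reported once per region and
    deduplicated within it.  Chromosomes present on only one side trigger a
    warning.
    """
    region_chroms = {r.chrom for r in regions}
    gene_chroms = set(genes["chrom"])
    unshared = sorted(region_chroms - gene_chroms)
    if unshared and len(genes):
        warnings.warn(
            "region chromosomes absent from the gene annotation: "
            + ", ".join(unshared),
            stacklevel=2,
        )
    rows = []
    for i, r in enumerate(regions):
        sub = genes[genes["chrom"] == r.chrom]
        hit = sub[(sub["start"] < r.end) & (sub["end"] > r.start)]
        for name in dict.fromkeys(hit["name"]):
            rows.append({
                "region_index": i, "chrom": r.chrom, "region_start": r.start,
                "region_end": r.end, "kind": r.kind, "gene": name,
            })
    return pd.DataFrame(
        rows,
        columns=[
            "region_index", "chrom", "region_start", "region_end",
            "kind", "gene",
        ],
    )


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED (first 4 columns) or GFF3 (gene features).

    GFF3 coordinates are converted to BED convention (0-based half-open);
    the gene name is taken from Name=, then gene_id=, then ID=.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
        rows = []
        for feat in db.features_of_type("gene"):
            name = (
                feat.attributes.get("Name", [None])[0]
                or feat.attributes.get("gene_id", [None])[0]
                or feat.id
            )
            rows.append((feat.seqid, feat.start - 1, feat.end, name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
    )
    return df
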