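"""Runs of identical window topologies and genomic bin counts.

A *run* is a maximal block of consecutive retained windows (ordinal order,
genomic gaps between retained windows ignored) sharing one topology class;
runs never span chromosome boundaries.  Long runs of a single topology are
the linkage signal that distinguishes introgressed haplotype blocks from
incomplete lineage sorting, which scatters discordant windows almost
independently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["Run", "detect_runs", "summarize_runs", "bin_counts"]


@dataclass(frozen=True)
class Run:
    class_key: str
    chrom: str
    start_ordinal: int  # ordinal of first window (global, 0-based)
    length: int  # number of windows
    start: int  # genomic span (BED)
    end: int


def detect_runs(windows: pd.DataFrame) -> list[Run]:
    """Maximal equal-class blocks over the ordered retained windows.

    ``windows`` needs columns chrom, start, end, class_key, ordered by
    (chrom, start); ordering is validated.  Runs partition the window
    sequence per chromosome.
    """
    required = {"chrom", "start", "end", "class_key"}
    if not required <= set(windows.columns):
        raise ValueError(f"windows must have columns {sorted(required)}")
    runs: list[Run] = []
    prev_chrom = None
    prev_start = None
    cur: dict | None = None
    for ordinal, row in enumerate(windows.itertuples(index=False)):
        if row.chrom == prev_chrom and row.start <= prev_start:
            raise ValueError(
                f"windows not ordered by (chrom, start) at ordinal {ordinal}"
            )
        new_chrom = row.chrom != prev_chrom
        prev_chrom, prev_start = row.chrom, row.start
        if cur is not None and not new_chrom and cur["key"] == row.class_key:
            cur["length"] += 1
            cur["end"] = row.end
            continue
        if cur is not None:
            runs.append(Run(
                class_key=cur["key"], chrom=cur["chrom"],
                start_ordinal=cur["ordinal"], length=cur["length"],
                start=cur["start"], end=cur["end"],
            ))
        cur = {
            "key": row.class_key, "chrom": row.chrom, "ordinal": ordinal,
            "length": 1, "start": row.start, "end": row.end,
        }
    if cur is not None:
        runs.append(Run(
            class_key=cur["key"], chrom=cur["chrom"],
            start_ordinal=cur["ordinal"], length=cur["length"],
            start=cur["start"], end=cur["end"],
        ))
    return runs


def summarize_runs(runs: Sequence[Run], k_high: int = 10) -> pd.DataFrame:
    """Per-class consecutive-window statistics.

    For each topology class: total windows, windows sitting in runs of
    length >= 2 and >= ``k_high``, the corresponding fractions, and the
    run-length histogram (mapping length -> windows, mass equal to the
    class total).
    """
    totals: Counter = Counter()
    ge2: Counter = Counter()
    gek: Counter = Counter()
    hists: dict[str, Counter] = {}
    for r in runs:
        totals[r.class_key] += r.length
        hists.setdefault(r.class_key, Counter())[r.length] += r.length
        if r.length >= 2:
            ge2[r.class_key] += r.length
        if r.length >= k_high:
            gek[r.class_key] += r.length
    rows = []
    for key in sorted(totals):
        t = totals[key]
        rows.append({
            "class_key": key,
            "total_windows": t,
            "windows_in_runs_ge2": ge2[key],
            "frac_in_runs_ge2": ge2[key] / t,
            f"windows_in_runs_ge{k_high}": gek[key],
            f"frac_in_runs_ge{k_high}": gek[key] / t,
            "run_length_histogram": dict(sorted(hists[key].items())),
        })
    return pd.DataFrame(rows)


def bin_counts(windows: pd.DataFrame, bin_size: int = 500_000) -> pd.DataFrame:
    """Topology counts per fixed genomic bin, intersect semantics.

    A window contributes to every bin it overlaps by >= 1 bp, so windows
    straddling a bin boundary are counted in both bins.  Columns of the
    result: chrom, bin_start, bin_end, class_key, count.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    counts: Counter = Counter()
    for row in windows.itertuples(index=False):
        first = row.start // bin_size
        last = (row.end - 1) // bin_size
        for b in range(first, last + 1):
            counts[(row.chrom, b * bin_size, row.class_key)] += 1
    rows = [
        {
            "chrom": chrom, "bin_start": bstart,
            "bin_end": bstart + bin_size, "class_key": key, "count": n,
        }
        for (chrom, bstart, key), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)
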