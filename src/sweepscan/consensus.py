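"""Consensus calling over the three flagged-window sets.

A window is a candidate when at least ``min_methods`` of the three scan
statistics (d_i, CLR, iHH12) place it in their empirical right tail; maximal
runs of genomically adjacent candidate windows merge into candidate regions.
Set logic only -- the raw statistics are never combined numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popio import IntervalSet, WindowGrid

METHODS = ("di", "clr", "ihh12")


@dataclass
class CandidateRegion:
    """Maximal run of adjacent consensus windows."""

    chrom: str
    start: int                        # 0-based half-open, window-aligned
    end: int
    methods: frozenset[str]           # union of support over member windows
    n_windows: int
    peaks: dict[str, float]           # per-method max window value in region

    @property
    def support_label(self) -> str:
        return ",".join(m for m in METHODS if m in self.methods)


def _check_flags(grid: WindowGrid, flags: dict[str, np.ndarray]) -> None:
    n = len(grid.windows)
    for method, f in flags.items():
        if np.asarray(f).shape != (n,):
            raise ValueError(
                f"flag set for {method!r} does not match the window grid "
                f"({np.asarray(f).shape} vs {n} windows)")


def consensus_windows(grid: WindowGrid, flags: dict[str, np.ndarray],
                      min_methods: int = 2) -> pd.DataFrame:
    """Windows flagged by >= min_methods methods, with per-window support.

    Returns the grid's windows plus one boolean column per method, the
    support count, a ``kept`` flag and a ``support`` label column.
    """
    _check_flags(grid, flags)
    out = grid.windows.copy()
    support = np.zeros(len(out), dtype=np.int64)
    for method in flags:
        col = np.asarray(flags[method], dtype=bool)
        out[method] = col
        support += col
    out["n_methods"] = support
    out["kept"] = support >= min_methods
    out["support"] = [
        ",".join(m for m in flags if bool(row[m])) for _, row in out.iterrows()]
    return out


def merge_adjacent(windows: pd.DataFrame,
                   window_values: dict[str, np.ndarray] | None = None
                   ) -> list[CandidateRegion]:
    """Merge kept windows into maximal runs of coordinate-adjacent windows.

    Adjacency is coordinate adjacency (end == next start on the same
    chromosome), so any intervening window -- unflagged or missing -- breaks
    a run.  ``window_values`` maps method -> per-window statistic values
    aligned with the grid, used for per-method peaks.
    """
    kept = windows[windows["kept"]]
    regions: list[CandidateRegion] = []
    run: list[int] = []

    def _flush() -> None:
        if not run:
            return
        rows = windows.loc[run]
        methods = frozenset(m for m in METHODS
                            if m in windows.columns and rows[m].any())
        peaks = {}
        if window_values:
            for m, vals in window_values.items():
                v = np.asarray(vals, dtype=np.float64)[run]
                peaks[m] = float(np.nanmax(v)) if np.isfinite(v).any() else float("nan")
        regions.append(CandidateRegion(
            str(rows.iloc[0]["chrom"]), int(rows.iloc[0]["start"]),
            int(rows.iloc[-1]["end"]), methods, len(run), peaks))

    for idx, row in kept.iterrows():
        if run and (windows.loc[run[-1], "chrom"] == row["chrom"]
                    and windows.loc[run[-1], "end"] == row["start"]):
            run.append(idx)
        else:
            _flush()
            run = [idx]
    _flush()
    return regions


def venn_counts(grid: WindowGrid, flags: dict[str, np.ndarray],
                level: str = "windows") -> dict[str, int]:
    """Counts of the 7 exclusive support classes (every non-empty subset of
    methods), over flagged windows (default) or merged single-method-minimum
    regions (``level="regions"``)."""
    _check_flags(grid, flags)
    methods = [m for m in METHODS if m in flags]
    if level == "windows":
        supports = []
        arrs = {m: np.asarray(flags[m], dtype=bool) for m in methods}
        any_flag = np.zeros(len(grid.windows), dtype=bool)
        for m in methods:
            any_flag |= arrs[m]
        for i in np.flatnonzero(any_flag):
            supports.append(frozenset(m for m in methods if arrs[m][i]))
    elif level == "regions":
        windows = consensus_windows(grid, flags, min_methods=1)
        supports = [r.methods for r in merge_adjacent(windows)]
    else:
        raise ValueError("level must be 'windows' or 'regions'")
    out: dict[str, int] = {}
    for size in (1, 2, 3):
        for combo in _subsets(methods, size):
            out[",".join(combo)] = sum(1 for s in supports if s == frozenset(combo))
    return out


def _subsets(methods: list[str], size: int):
    from itertools import combinations
    return combinations(methods, size)


def regions_to_intervals(regions: list[CandidateRegion]) -> IntervalSet:
    rows = [(r.chrom, r.start, r.end, r.support_label, r.n_windows)
            for r in regions]
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                   "name", "score"]))
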