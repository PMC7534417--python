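"""iHH12: integrated top-two-pooled haplotype homozygosity.

EHH12 at flanking site x measures, for the haplotype partition induced by
identity over the closed site interval [core..x], the probability that two
randomly drawn haplotypes fall in the same class after pooling the two
largest classes:

    EHH12 = [C(n1 + n2, 2) + sum_{k>=3} C(n_k, 2)] / C(H, 2)

with class sizes n1 >= n2 >= ... over H haplotypes.  Pooling the two largest
classes keeps power when a sweep carries two frequent haplotypes (soft-ish
sweeps).  iHH12 is the trapezoidal integral of the EHH12 decay curve against
physical distance, extended marker by marker in both directions until EHH12
falls below a cutoff (default 0.05); the genome-wide z-score of iHH12 is the
scan statistic.

Physical distance stands in for genetic distance (uniform map), matching the
simulator's constant recombination rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popio import Genome, HaplotypeMatrix, WindowGrid
from .fst import empirical_threshold, window_max, window_mean

log = logging.getLogger("sweepscan")

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000
DEFAULT_MAX_EXTEND = 1_000_000


def _pairs(x: np.ndarray | float) -> np.ndarray | float:
    return x * (x - 1) / 2.0


def ehh12_from_sizes(sizes, n_hap: int) -> float:
    """EHH12 from haplotype-class sizes (any order)."""
    if n_hap < 2:
        raise ValueError("need at least 2 haplotypes")
    s = np.sort(np.asarray(sizes, dtype=np.float64))[::-1]
    if s.size == 0 or s.sum() != n_hap:
        raise ValueError("class sizes must partition the haplotypes")
    top2 = s[0] + (s[1] if s.size > 1 else 0.0)
    rest = _pairs(s[2:]).sum() if s.size > 2 else 0.0
    return float((_pairs(top2) + rest) / _pairs(float(n_hap)))


def ehh12_at(hap: HaplotypeMatrix, core: int, x: int) -> float:
    """EHH12 for the partition over the closed site interval [core..x].

    At x == core the partition is by core-site allele; top-two pooling then
    gives exactly 1 for a biallelic (or monomorphic) core.
    """
    hap.require_phased()
    H = hap.n_haplotypes
    if H < 2:
        raise ValueError("need at least 2 haplotypes")
    lo, hi = min(core, x), max(core, x)
    block = hap.alleles[:, lo:hi + 1]
    _, counts = np.unique(block, axis=0, return_counts=True)
    return ehh12_from_sizes(counts, H)


@dataclass
class EHHDecayCurve:
    """EHH12 evaluated at every marker from the core outwards."""

    core: int
    direction: str                    # "left" | "right"
    distances: np.ndarray             # bp from core, starting at 0
    values: np.ndarray                # EHH12, values[0] == 1

    def __post_init__(self) -> None:
        if np.any(np.diff(self.values) > 1e-12):
            raise AssertionError("EHH12 decay curve must be non-increasing")


def ehh12_curve(hap: HaplotypeMatrix, core: int, direction: str) -> EHHDecayCurve:
    """Full decay curve (marker-by-marker, no cutoff) in one direction."""
    step = 1 if direction == "right" else -1
    idx = range(core, hap.n_sites if direction == "right" else -1, step)
    dists, vals = [], []
    for x in idx:
        dists.append(abs(int(hap.positions[x]) - int(hap.positions[core])))
        vals.append(ehh12_at(hap, core, x))
    return EHHDecayCurve(core, direction, np.array(dists, dtype=np.float64),
                         np.array(vals))


# ---------------------------------------------------------------------------
# Raw iHH12 per core
# ---------------------------------------------------------------------------

def _ehh12_of_gid(gid: np.ndarray, denom: float) -> tuple[np.ndarray, float]:
    """Compress group ids and return (compressed gid, EHH12)."""
    _, gid = np.unique(gid, return_inverse=True)
    s = np.sort(np.bincount(gid))[::-1]
    top2 = s[0] + (s[1] if s.size > 1 else 0)
    rest = _pairs(s[2:].astype(np.float64)).sum() if s.size > 2 else 0.0
    return gid, float((_pairs(float(top2)) + rest) / denom)


def _direction_ihh12(positions: np.ndarray, alleles: np.ndarray, core: int,
                     right: bool, cutoff: float, max_gap: int,
                     max_extend: int, edge_ok: bool = False) -> float:
    """Trapezoidal integral of the EHH12 decay curve on one side of the core.

    Extends marker by marker away from the core until EHH12 < cutoff,
    truncating the final trapezoid at the cutoff crossing by linear
    interpolation (or at max_extend, whichever comes first).  Returns NaN if
    the chromosome edge or an inter-marker gap > max_gap is reached before
    the cutoff.
    """
    H, S = alleles.shape
    denom = _pairs(float(H))
    core_pos = int(positions[core])
    step = 1 if right else -1
    last = S - 1 if right else 0

    gid = alleles[:, core].astype(np.int64)
    e_prev = 1.0          # pooled top-two classes of a biallelic core
    area = 0.0
    d_prev = 0.0
    x = core
    while x != last:
        nx = x + step
        d_new = abs(int(positions[nx]) - core_pos)
        if abs(int(positions[nx]) - int(positions[x])) > max_gap:
            return np.nan
        gid, e_new = _ehh12_of_gid(gid * 2 + alleles[:, nx], denom)
        if e_new > e_prev + 1e-12:
            raise AssertionError("EHH12 increased while extending")
        d_cut = np.inf
        if e_new < cutoff:
            d_cut = d_prev + (e_prev - cutoff) / (e_prev - e_new) * (d_new - d_prev)
        d_stop = min(d_cut, float(max_extend))
        if d_stop <= d_new:
            if d_stop == d_cut:
                e_stop = cutoff
            else:
                e_stop = e_prev + (d_stop - d_prev) / (d_new - d_prev) * (e_new - e_prev)
            return area + 0.5 * (e_prev + e_stop) * (d_stop - d_prev)
        area += 0.5 * (e_prev + e_new) * (d_new - d_prev)
        e_prev, d_prev, x = e_new, d_new, nx
    # chromosome edge reached with EHH12 still >= cutoff
    return area if edge_ok else np.nan


def ihh12_site(hap: HaplotypeMatrix, core: int,
               cutoff: float = DEFAULT_CUTOFF,
               max_gap: int = DEFAULT_MAX_GAP,
               max_extend: int = DEFAULT_MAX_EXTEND,
               edge_ok: bool = False) -> float:
    """Raw iHH12 (bp units) for one core site; NaN if either direction hits
    the chromosome edge or a gap > max_gap before reaching the cutoff.

    ``edge_ok`` truncates the integral at the chromosome edge instead of
    marking the core missing -- the standard option for contigs that are
    short relative to the haplotype-homozygosity decay length.
    """
    hap.require_phased()
    left = _direction_ihh12(hap.positions, hap.alleles, core, False,
                            cutoff, max_gap, max_extend, edge_ok)
    right = _direction_ihh12(hap.positions, hap.alleles, core, True,
                             cutoff, max_gap, max_extend, edge_ok)
    return left + right  # NaN propagates


def _span_gap_bad(positions: np.ndarray, lo: int, hi: int, max_gap: int) -> bool:
    seg = positions[lo:hi + 1]
    return seg.size >= 2 and int(np.max(np.diff(seg))) > max_gap


def _extend_stop_index(positions: np.ndarray, core_pos: int, right: bool,
                       max_extend: int) -> int:
    """Index of the first marker (moving outwards) at distance >= max_extend."""
    if right:
        return int(np.searchsorted(positions, core_pos + max_extend, "left"))
    return int(np.searchsorted(positions, core_pos - max_extend, "right")) - 1


def _direction_ihh12_fast(positions: np.ndarray, alleles: np.ndarray,
                          informative: np.ndarray, core: int, right: bool,
                          cutoff: float, max_gap: int, max_extend: int,
                          need_gap_check: bool, edge_ok: bool = False) -> float:
    """Same contract as :func:`_direction_ihh12`, but jumps directly between
    columns polymorphic in the sample: across a run of monomorphic columns
    the partition -- hence EHH12 -- is constant, so those per-marker
    trapezoids collapse exactly into one rectangle."""
    H, S = alleles.shape
    denom = _pairs(float(H))
    core_pos = int(positions[core])
    if right:
        seq = informative[np.searchsorted(informative, core, side="right"):]
    else:
        seq = informative[:np.searchsorted(informative, core, side="left")][::-1]

    gid = alleles[:, core].astype(np.int64)
    e_prev = 1.0
    area = 0.0
    d_prev = 0.0
    prev_idx = core
    for j in map(int, seq):
        jm1 = j - 1 if right else j + 1       # marker adjacent to j, core side
        d_mid = abs(int(positions[jm1]) - core_pos)
        d_new = abs(int(positions[j]) - core_pos)
        if d_mid >= max_extend:
            # truncation falls inside the constant-EHH run before j
            if need_gap_check:
                m = _extend_stop_index(positions, core_pos, right, max_extend)
                lo, hi = (prev_idx, m) if right else (m, prev_idx)
                if _span_gap_bad(positions, lo, hi, max_gap):
                    return np.nan
            return area + e_prev * (max_extend - d_prev)
        gid, e_new = _ehh12_of_gid(gid * 2 + alleles[:, j], denom)
        if e_new > e_prev + 1e-12:
            raise AssertionError("EHH12 increased while extending")
        d_cut = np.inf
        if e_new < cutoff:
            d_cut = d_mid + (e_prev - cutoff) / (e_prev - e_new) * (d_new - d_mid)
        d_stop = min(d_cut, float(max_extend))
        if need_gap_check:
            lo, hi = (prev_idx, j) if right else (j, prev_idx)
            if _span_gap_bad(positions, lo, hi, max_gap):
                return np.nan
        if d_stop <= d_new:
            if d_stop == d_cut:
                e_stop = cutoff
            else:
                e_stop = e_prev + (d_stop - d_mid) / (d_new - d_mid) * (e_new - e_prev)
            return (area + e_prev * (d_mid - d_prev)
                    + 0.5 * (e_prev + e_stop) * (d_stop - d_mid))
        area += e_prev * (d_mid - d_prev) + 0.5 * (e_prev + e_new) * (d_new - d_mid)
        e_prev, d_prev, prev_idx = e_new, d_new, j

    # past the last informative marker EHH12 stays e_prev (>= cutoff)
    last = S - 1 if right else 0
    d_last = abs(int(positions[last]) - core_pos)
    if d_last >= max_extend:
        if need_gap_check:
            m = _extend_stop_index(positions, core_pos, right, max_extend)
            lo, hi = (prev_idx, m) if right else (m, prev_idx)
            if _span_gap_bad(positions, lo, hi, max_gap):
                return np.nan
        return area + e_prev * (max_extend - d_prev)
    if edge_ok:
        if need_gap_check:
            lo, hi = (prev_idx, last) if right else (last, prev_idx)
            if _span_gap_bad(positions, lo, hi, max_gap):
                return np.nan
        return area + e_prev * (d_last - d_prev)
    return np.nan  # chromosome edge reached with EHH12 still >= cutoff


try:  # compiled kernel; the pure-Python walk remains the reference path
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True)
def _dir_kernel(positions, alleles, informative, core, right, cutoff,
                max_gap, max_extend, need_gap, edge_ok,
                gid, gid2, cnt, remap):
    H, S = alleles.shape
    denom = H * (H - 1) * 0.5
    core_pos = positions[core]
    if right:
        ii = np.searchsorted(informative, core, side="right")
        i_end = informative.size
        stepi = 1
    else:
        ii = np.searchsorted(informative, core, side="left") - 1
        i_end = -1
        stepi = -1

    for h in range(H):
        gid[h] = alleles[h, core]
    G = 2
    e_prev = 1.0
    d_prev = 0.0
    area = 0.0
    prev_idx = core
    while ii != i_end:
        j = informative[ii]
        jm1 = j - 1 if right else j + 1
        d_mid = abs(positions[jm1] - core_pos)
        d_new = abs(positions[j] - core_pos)
        if d_mid >= max_extend:
            if need_gap:
                if right:
                    m = np.searchsorted(positions, core_pos + max_extend,
                                        side="left")
                    lo, hi = prev_idx, m
                else:
                    m = np.searchsorted(positions, core_pos - max_extend,
                                        side="right") - 1
                    lo, hi = m, prev_idx
                for t in range(lo, hi):
                    if positions[t + 1] - positions[t] > max_gap:
                        return np.nan
            return area + e_prev * (max_extend - d_prev)

        for h in range(H):
            gid2[h] = gid[h] * 2 + alleles[h, j]
        for g in range(2 * G):
            cnt[g] = 0
        for h in range(H):
            cnt[gid2[h]] += 1
        newG = 0
        top1 = 0
        top2 = 0
        pairs = 0.0
        for g in range(2 * G):
            c = cnt[g]
            if c > 0:
                remap[g] = newG
                newG += 1
                pairs += c * (c - 1) * 0.5
                if c > top1:
                    top2 = top1
                    top1 = c
                elif c > top2:
                    top2 = c
        for h in range(H):
            gid[h] = remap[gid2[h]]
        G = newG
        t12 = top1 + top2
        e_new = (t12 * (t12 - 1) * 0.5 + pairs - top1 * (top1 - 1) * 0.5
                 - top2 * (top2 - 1) * 0.5) / denom

        d_cut = 1e300
        if e_new < cutoff:
            d_cut = d_mid + (e_prev - cutoff) / (e_prev - e_new) * (d_new - d_mid)
        d_stop = d_cut if d_cut < max_extend else float(max_extend)
        if need_gap:
            if right:
                lo, hi = prev_idx, j
            else:
                lo, hi = j, prev_idx
            for t in range(lo, hi):
                if positions[t + 1] - positions[t] > max_gap:
                    return np.nan
        if d_stop <= d_new:
            if d_stop == d_cut:
                e_stop = cutoff
            else:
                e_stop = e_prev + (d_stop - d_mid) / (d_new - d_mid) * (e_new - e_prev)
            return (area + e_prev * (d_mid - d_prev)
                    + 0.5 * (e_prev + e_stop) * (d_stop - d_mid))
        area += e_prev * (d_mid - d_prev) + 0.5 * (e_prev + e_new) * (d_new - d_mid)
        e_prev = e_new
        d_prev = float(d_new)
        prev_idx = j
        ii += stepi

    last = S - 1 if right else 0
    d_last = abs(positions[last] - core_pos)
    if d_last >= max_extend:
        if need_gap:
            if right:
                m = np.searchsorted(positions, core_pos + max_extend,
                                    side="left")
                lo, hi = prev_idx, m
            else:
                m = np.searchsorted(positions, core_pos - max_extend,
                                    side="right") - 1
                lo, hi = m, prev_idx
            for t in range(lo, hi):
                if positions[t + 1] - positions[t] > max_gap:
                    return np.nan
        return area + e_prev * (max_extend - d_prev)
    if edge_ok:
        if need_gap:
            if right:
                lo, hi = prev_idx, last
            else:
                lo, hi = last, prev_idx
            for t in range(lo, hi):
                if positions[t + 1] - positions[t] > max_gap:
                    return np.nan
        return area + e_prev * (d_last - d_prev)
    return np.nan


@_njit(cache=True)
def _ihh12_kernel(positions, alleles, informative, cutoff, max_gap,
                  max_extend, need_gap, edge_ok):
    H, S = alleles.shape
    out = np.empty(S)
    gid = np.empty(H, np.int64)
    gid2 = np.empty(H, np.int64)
    cnt = np.zeros(2 * H + 2, np.int64)
    remap = np.zeros(2 * H + 2, np.int64)
    for core in range(S):
        left = _dir_kernel(positions, alleles, informative, core, False,
                           cutoff, max_gap, max_extend, need_gap, edge_ok,
                           gid, gid2, cnt, remap)
        if np.isnan(left):
            out[core] = np.nan
            continue
        right = _dir_kernel(positions, alleles, informative, core, True,
                            cutoff, max_gap, max_extend, need_gap, edge_ok,
                            gid, gid2, cnt, remap)
        out[core] = left + right
    return out


def _chrom_ihh12_python(hap: HaplotypeMatrix, cutoff: float, max_gap: int,
                        max_extend: int, edge_ok: bool = False) -> np.ndarray:
    counts = hap.alleles.sum(axis=0, dtype=np.int64)
    informative = np.flatnonzero((counts > 0) & (counts < hap.n_haplotypes))
    gaps = np.diff(hap.positions)
    need_gap_check = bool(gaps.size and gaps.max() > max_gap)
    out = np.empty(hap.n_sites)
    for core in range(hap.n_sites):
        left = _direction_ihh12_fast(hap.positions, hap.alleles, informative,
                                     core, False, cutoff, max_gap, max_extend,
                                     need_gap_check, edge_ok)
        if np.isnan(left):
            out[core] = np.nan
            continue
        right = _direction_ihh12_fast(hap.positions, hap.alleles, informative,
                                      core, True, cutoff, max_gap, max_extend,
                                      need_gap_check, edge_ok)
        out[core] = left + right
    return out


def _chrom_ihh12_fast(hap: HaplotypeMatrix, cutoff: float, max_gap: int,
                      max_extend: int, edge_ok: bool = False) -> np.ndarray:
    """Per-site raw iHH12 for a whole chromosome (compiled when numba is
    available; equals :func:`ihh12_site` at every site)."""
    if not _HAVE_NUMBA:  # pragma: no cover
        return _chrom_ihh12_python(hap, cutoff, max_gap, max_extend, edge_ok)
    counts = hap.alleles.sum(axis=0, dtype=np.int64)
    informative = np.flatnonzero((counts > 0) & (counts < hap.n_haplotypes))
    gaps = np.diff(hap.positions)
    need_gap_check = bool(gaps.size and gaps.max() > max_gap)
    return _ihh12_kernel(np.ascontiguousarray(hap.positions, dtype=np.int64),
                         np.ascontiguousarray(hap.alleles),
                         informative.astype(np.int64), float(cutoff),
                         int(max_gap), int(max_extend), need_gap_check,
                         bool(edge_ok))


# ---------------------------------------------------------------------------
# Normalization and windows
# ---------------------------------------------------------------------------

@dataclass
class IHH12Track:
    sites: pd.DataFrame               # chrom, pos, raw, norm
    mean: float                       # E[iHH12] over defined sites
    sd: float                         # population sd (ddof=0)


def ihh12_track(genome: Genome, cutoff: float = DEFAULT_CUTOFF,
                max_gap: int = DEFAULT_MAX_GAP,
                max_extend: int = DEFAULT_MAX_EXTEND,
                edge_ok: bool = False) -> pd.DataFrame:
    """Raw iHH12 for every site of every chromosome (chrom, pos, raw)."""
    frames = []
    for chrom, hap in genome.items():
        raw = _chrom_ihh12_fast(hap, cutoff, max_gap, max_extend, edge_ok)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": hap.positions,
                                    "raw": raw}))
    return pd.concat(frames, ignore_index=True)


def normalize_ihh12(raw_track: pd.DataFrame) -> IHH12Track:
    """Genome-wide z-score: (iHH12 - E[iHH12]) / sd[iHH12], single pool."""
    vals = raw_track["raw"].to_numpy(dtype=np.float64)
    defined = np.isfinite(vals)
    if defined.sum() < 2:
        raise ValueError("need >= 2 defined iHH12 values to normalize")
    mean = float(vals[defined].mean())
    sd = float(vals[defined].std(ddof=0))
    if sd == 0.0:
        raise ValueError("degenerate iHH12 distribution: sd = 0")
    out = raw_track.copy()
    out["norm"] = (vals - mean) / sd
    return IHH12Track(out, mean, sd)


def window_summary_ihh12(track: IHH12Track, grid: WindowGrid,
                         stat: str = "mean", min_sites: int = 10) -> pd.DataFrame:
    """Per-window mean (default) or max of normalized iHH12 over defined cores."""
    sites = track.sites
    if stat == "mean":
        return window_mean(sites, grid, "norm", min_sites=min_sites)
    if stat == "max":
        return window_max(sites, grid, "norm", min_sites=min_sites)
    raise ValueError("stat must be 'mean' or 'max'")


@dataclass
class IHH12ScanResult:
    track: IHH12Track
    window: pd.DataFrame
    threshold: float
    flags: np.ndarray


def ihh12_scan(focal_genome: Genome, grid: WindowGrid,
               cutoff: float = DEFAULT_CUTOFF, max_gap: int = DEFAULT_MAX_GAP,
               max_extend: int = DEFAULT_MAX_EXTEND, tail: float = 0.05,
               window_stat: str = "mean", min_sites: int = 10,
               edge_ok: bool = False) -> IHH12ScanResult:
    raw = ihh12_track(focal_genome, cutoff, max_gap, max_extend, edge_ok)
    track = normalize_ihh12(raw)
    window = window_summary_ihh12(track, grid, stat=window_stat,
                                  min_sites=min_sites)
    threshold, flags = empirical_threshold(window, tail=tail)
    return IHH12ScanResult(track, window, threshold, flags)
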