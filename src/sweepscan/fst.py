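"""Per-SNP Weir & Cockerham F_ST, the d_i differentiation statistic, window
averaging and empirical right-tail thresholding.

d_i sums, over the reference populations j, the z-standardized pairwise F_ST
between the focal population i and j:

    d_i = sum_j (F_ST^{ij} - E[F_ST^{ij}]) / sd[F_ST^{ij}]

with the expectation and standard deviation taken over all autosomal SNVs.
Large d_i marks loci whose differentiation of the focal lineage is extreme
relative to its genome-wide background.  Windowed values are averaged over
the SNVs in each non-overlapping window (default 100 kb) and the empirical
5% right tail is flagged as candidate windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popio import DEFAULT_AUTOSOMES, Genome, WindowGrid

log = logging.getLogger("sweepscan")


# ---------------------------------------------------------------------------
# Per-site F_ST (Weir & Cockerham 1984 theta-hat, two populations)
# ---------------------------------------------------------------------------

def pop_site_counts(hap) -> tuple[int, np.ndarray, np.ndarray]:
    """(diploid count, per-site alt-allele count, per-site heterozygote count)
    for one population's haplotype matrix (rows 2k, 2k+1 = diploid k)."""
    a = hap.alleles
    n_dip = a.shape[0] // 2
    alt = a.sum(axis=0, dtype=np.int64)
    het = (a[0::2] != a[1::2]).sum(axis=0, dtype=np.int64)
    return n_dip, alt, het


def weir_cockerham_fst(alt1, n1, het1, alt2, n2, het2) -> np.ndarray:
    """Single-locus two-population WC84 theta-hat = a / (a + b + c).

    Inputs are alt-allele counts, diploid sample sizes and observed
    heterozygote counts; all may be arrays.  Returns NaN where the estimator
    is undefined (0/0: both populations monomorphic for the same allele) or
    where a sample has fewer than 2 diploids.
    """
    alt1 = np.asarray(alt1, dtype=np.float64)
    alt2 = np.asarray(alt2, dtype=np.float64)
    het1 = np.asarray(het1, dtype=np.float64)
    het2 = np.asarray(het2, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)

    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt1 / (2 * n1)
        p2 = alt2 / (2 * n2)
        h1 = het1 / n1
        h2 = het2 / n2
        r = 2.0
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0)
            / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - (r - 1.0) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0.0, a / denom, np.nan)
    theta = np.where((n1 < 2) | (n2 < 2), np.nan, theta)
    return theta


def site_fst(alt1: int, n1: int, het1: int,
             alt2: int, n2: int, het2: int) -> float:
    return float(weir_cockerham_fst(alt1, n1, het1, alt2, n2, het2))


def hudson_fst(alt1, n1, het1, alt2, n2, het2) -> np.ndarray:
    """Hudson-style estimator (sensitivity switch): 1 - Hw/Hb from haplotype
    allele frequencies; het counts are accepted for interface parity."""
    alt1 = np.asarray(alt1, dtype=np.float64)
    alt2 = np.asarray(alt2, dtype=np.float64)
    m1 = 2 * np.asarray(n1, dtype=np.float64)
    m2 = 2 * np.asarray(n2, dtype=np.float64)
    p1, p2 = alt1 / m1, alt2 / m2
    with np.errstate(invalid="ignore", divide="ignore"):
        hw = (p1 * (m1 - alt1) / (m1 - 1) + p2 * (m2 - alt2) / (m2 - 1))
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        out = np.where(hb != 0.0, 1.0 - hw / hb, np.nan)
    return np.where((np.asarray(n1) < 2) | (np.asarray(n2) < 2), np.nan, out)


_ESTIMATORS = {"wc84": weir_cockerham_fst, "hudson": hudson_fst}


def fst_track(focal: Genome, reference: Genome,
              estimator: str = "wc84") -> pd.DataFrame:
    """Per-site pairwise F_ST; DataFrame with columns chrom, pos, fst."""
    est = _ESTIMATORS[estimator]
    frames = []
    for chrom, hf in focal.items():
        hr = reference[chrom]
        if not np.array_equal(hf.positions, hr.positions):
            raise ValueError(f"{chrom}: focal/reference site lists differ")
        n1, alt1, het1 = pop_site_counts(hf)
        n2, alt2, het2 = pop_site_counts(hr)
        vals = est(alt1, np.full_like(alt1, n1), het1,
                   alt2, np.full_like(alt2, n2), het2)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": hf.positions,
                                    "fst": vals}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# d_i
# ---------------------------------------------------------------------------

@dataclass
class StandardizationConstants:
    """Genome-wide (autosomal) mean and sd of per-SNP pairwise F_ST."""

    mean: float
    sd: float           # population sd (ddof=0), so addend variance is 1
    n_sites: int

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("degenerate F_ST distribution: sd must be > 0")


def standardization_constants(track: pd.DataFrame,
                              autosomes: tuple[str, ...] = DEFAULT_AUTOSOMES
                              ) -> StandardizationConstants:
    """Mean/sd of defined per-SNP F_ST over autosomal sites only."""
    sel = track["chrom"].isin(autosomes)
    vals = track.loc[sel, "fst"].to_numpy(dtype=np.float64)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need >= 2 defined autosomal F_ST values")
    return StandardizationConstants(float(vals.mean()),
                                    float(vals.std(ddof=0)), vals.size)


def di_per_site(fst_tracks: dict[str, pd.DataFrame],
                consts: dict[str, StandardizationConstants]) -> pd.DataFrame:
    """Sum of standardized pairwise F_ST per site -> columns chrom, pos, di.

    A site missing (NaN) in any pair is missing in d_i.
    """
    refs = list(fst_tracks)
    if set(refs) != set(consts):
        raise ValueError("fst_tracks and consts must cover the same references")
    base = fst_tracks[refs[0]][["chrom", "pos"]]
    total = np.zeros(len(base), dtype=np.float64)
    for ref in refs:
        tr = fst_tracks[ref]
        if not (tr["chrom"].equals(base["chrom"]) and tr["pos"].equals(base["pos"])):
            raise ValueError("pairwise F_ST tracks must share identical site lists")
        c = consts[ref]
        total = total + (tr["fst"].to_numpy(dtype=np.float64) - c.mean) / c.sd
    out = base.copy()
    out["di"] = total
    return out


# ---------------------------------------------------------------------------
# Windowing and thresholding (shared by all three statistics)
# ---------------------------------------------------------------------------

def window_mean(track: pd.DataFrame, grid: WindowGrid, value_col: str,
                min_sites: int = 10) -> pd.DataFrame:
    """Arithmetic mean of defined per-site values per window.

    Windows with fewer than ``min_sites`` contributing (defined) sites are
    flagged missing (NaN value), never 0.  Returns the grid's windows with
    ``value`` and ``n_sites`` columns.
    """
    out = grid.windows.copy()
    sums = np.zeros(len(out))
    counts = np.zeros(len(out), dtype=np.int64)
    for chrom, sub in track.groupby("chrom", sort=False):
        if chrom not in grid.chrom_lengths:
            raise ValueError(f"grid does not cover chromosome {chrom!r}")
        vals = sub[value_col].to_numpy(dtype=np.float64)
        ok = np.isfinite(vals)
        idx = grid.window_index(chrom, sub["pos"].to_numpy()[ok])
        np.add.at(sums, idx, vals[ok])
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        value = np.where(counts >= max(min_sites, 1), sums / counts, np.nan)
    out["value"] = value
    out["n_sites"] = counts
    return out


def window_max(track: pd.DataFrame, grid: WindowGrid, value_col: str,
               min_sites: int = 1) -> pd.DataFrame:
    """Per-window maximum of defined per-site values (reduction switch)."""
    out = grid.windows.copy()
    best = np.full(len(out), -np.inf)
    counts = np.zeros(len(out), dtype=np.int64)
    for chrom, sub in track.groupby("chrom", sort=False):
        if chrom not in grid.chrom_lengths:
            raise ValueError(f"grid does not cover chromosome {chrom!r}")
        vals = sub[value_col].to_numpy(dtype=np.float64)
        ok = np.isfinite(vals)
        idx = grid.window_index(chrom, sub["pos"].to_numpy()[ok])
        np.maximum.at(best, idx, vals[ok])
        np.add.at(counts, idx, 1)
    value = np.where(counts >= max(min_sites, 1), best, np.nan)
    out["value"] = value
    out["n_sites"] = counts
    return out


def empirical_threshold(wtrack: pd.DataFrame, tail: float = 0.05
                        ) -> tuple[float, np.ndarray]:
    """Empirical right-tail threshold over defined window values.

    The threshold is the (1 - tail) empirical quantile of type "higher" (the
    smallest observed value with at least (1 - tail) of the mass at or below
    it); flagged windows are those strictly greater.  Missing windows are
    excluded from both the quantile and the flags.
    """
    if not 0.0 < tail < 1.0:
        raise ValueError("tail must lie in (0, 1)")
    vals = wtrack["value"].to_numpy(dtype=np.float64)
    defined = np.isfinite(vals)
    m = int(defined.sum())
    need = math.ceil(1.0 / tail)  # 20 for the default 5% tail
    if m < need:
        raise ValueError(f"only {m} defined windows; need >= {need} for a "
                         f"meaningful {tail:.0%} tail")
    svals = np.sort(vals[defined])
    k = math.ceil((1.0 - tail) * m)
    threshold = float(svals[k - 1])
    flags = defined & (vals > threshold)
    return threshold, flags


# ---------------------------------------------------------------------------
# Full d_i scan
# ---------------------------------------------------------------------------

@dataclass
class DiScanResult:
    site_fst: dict[str, pd.DataFrame]            # per reference
    constants: dict[str, StandardizationConstants]
    site_di: pd.DataFrame
    window_di: pd.DataFrame
    threshold: float
    flags: np.ndarray


def di_scan(pop_genomes: dict[str, Genome], focal: str, refs: list[str],
            grid: WindowGrid, tail: float = 0.05, min_sites: int = 10,
            autosomes: tuple[str, ...] | None = None,
            estimator: str = "wc84") -> DiScanResult:
    """Run the whole d_i stage: pairwise F_ST, standardization from autosomes,
    per-site d_i, window means and 5%-tail flags.

    ``autosomes`` defaults to chromosome names "1".."18"; pass the full
    chromosome set explicitly for other genomes.  Non-autosomal windows are
    excluded from threshold calibration (their flags are NaN-safe False).
    """
    if len(refs) < 1:
        raise ValueError("at least one reference population is required")
    if autosomes is None:
        autosomes = DEFAULT_AUTOSOMES
    tracks = {ref: fst_track(pop_genomes[focal], pop_genomes[ref], estimator)
              for ref in refs}
    consts = {ref: standardization_constants(tr, autosomes)
              for ref, tr in tracks.items()}
    site_di = di_per_site(tracks, consts)
    window_di = window_mean(site_di, grid, "di", min_sites=min_sites)
    calib = window_di.copy()
    calib.loc[~calib["chrom"].isin(autosomes), "value"] = np.nan
    threshold, flags = empirical_threshold(calib, tail=tail)
    return DiScanResult(tracks, consts, site_di, window_di, threshold, flags)
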