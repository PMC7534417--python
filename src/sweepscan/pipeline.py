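"""End-to-end scan: MAF filter -> d_i + iHH12 + CLR -> consensus -> regions.

All three statistics share one window grid and one empirical-threshold rule;
the consensus keeps windows flagged by at least two methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import clr as clr_mod
from . import consensus as cons_mod
from . import ehh as ehh_mod
from . import fst as fst_mod
from .popio import Genome, PopulationMap, WindowGrid, filter_maf_genome

log = logging.getLogger("sweepscan")


@dataclass
class ScanConfig:
    """Resolved parameters of a full scan (serialized next to outputs)."""

    window_size: int = 100_000
    tail: float = 0.05
    min_sites: int = 10
    maf_min: float = 0.01
    min_methods: int = 2
    autosomes: tuple[str, ...] | None = None   # None -> "1".."18"
    fst_estimator: str = "wc84"
    ihh12_cutoff: float = ehh_mod.DEFAULT_CUTOFF
    ihh12_max_gap: int = ehh_mod.DEFAULT_MAX_GAP
    ihh12_max_extend: int = ehh_mod.DEFAULT_MAX_EXTEND
    ihh12_window_stat: str = "mean"
    ihh12_edge_ok: bool = False
    clr_grid_step: int = clr_mod.DEFAULT_GRID_STEP
    clr_flank: int = clr_mod.DEFAULT_FLANK
    clr_alpha_grid: tuple[float, ...] = clr_mod.DEFAULT_ALPHA_GRID
    clr_folded: bool = False
    clr_include_invariant: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FullScanResult:
    config: ScanConfig
    grid: WindowGrid
    di: fst_mod.DiScanResult
    ihh12: ehh_mod.IHH12ScanResult
    clr: clr_mod.CLRScanResult
    windows: "object"                         # consensus window table
    regions: list[cons_mod.CandidateRegion]
    venn: dict[str, int]

    @property
    def flags(self) -> dict[str, np.ndarray]:
        return {"di": self.di.flags, "clr": self.clr.flags,
                "ihh12": self.ihh12.flags}


def full_scan(genome: Genome, popmap: PopulationMap, focal: str,
              refs: list[str], chrom_lengths: dict[str, int],
              config: ScanConfig | None = None) -> FullScanResult:
    """Run the three scans and consensus on an already-phased genome."""
    config = config or ScanConfig()
    log.info("full_scan: MAF filter > %g", config.maf_min)
    genome = filter_maf_genome(genome, config.maf_min)
    grid = WindowGrid(dict(chrom_lengths), config.window_size)
    pops = {p: {c: h.subset_samples(popmap.samples(p))
                for c, h in genome.items()}
            for p in [focal, *refs]}
    autosomes = config.autosomes
    if autosomes is None:
        autosomes = tuple(c for c in chrom_lengths
                          if c in fst_mod.DEFAULT_AUTOSOMES)

    log.info("full_scan: d_i stage (focal=%s refs=%s)", focal, refs)
    di = fst_mod.di_scan(pops, focal, refs, grid, tail=config.tail,
                         min_sites=config.min_sites, autosomes=autosomes,
                         estimator=config.fst_estimator)
    log.info("full_scan: iHH12 stage")
    ihh = ehh_mod.ihh12_scan(pops[focal], grid, cutoff=config.ihh12_cutoff,
                             max_gap=config.ihh12_max_gap,
                             max_extend=config.ihh12_max_extend,
                             tail=config.tail,
                             window_stat=config.ihh12_window_stat,
                             min_sites=config.min_sites,
                             edge_ok=config.ihh12_edge_ok)
    log.info("full_scan: CLR stage")
    clr = clr_mod.clr_scan(pops[focal], grid, grid_step=config.clr_grid_step,
                           flank=config.clr_flank,
                           alpha_grid=config.clr_alpha_grid,
                           folded=config.clr_folded,
                           include_invariant=config.clr_include_invariant,
                           tail=config.tail)
    flags = {"di": di.flags, "clr": clr.flags, "ihh12": ihh.flags}
    windows = cons_mod.consensus_windows(grid, flags,
                                         min_methods=config.min_methods)
    values = {"di": di.window_di["value"].to_numpy(),
              "clr": clr.window["value"].to_numpy(),
              "ihh12": ihh.window["value"].to_numpy()}
    regions = cons_mod.merge_adjacent(windows, values)
    venn = cons_mod.venn_counts(grid, flags)
    log.info("full_scan: %d consensus windows -> %d regions",
             int(windows["kept"].sum()), len(regions))
    return FullScanResult(config, grid, di, ihh, clr, windows, regions, venn)
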