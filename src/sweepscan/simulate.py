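"""Forward Wright-Fisher simulator for truth-known multi-population sweep data.

Emulates the three-population sampling design behind the scan (one focal
population, two diverged references): an ancestral diploid population of size
``n_e`` evolves a burn-in of ``burn_in_factor * n_e`` discrete generations from
a monomorphic start (approximate mutation-drift equilibrium at desk scales),
then splits into three isolated populations that drift apart for
``split_gens`` generations.  Each generation applies per-genome Poisson
mutation under an infinite-sites rule (collision positions are redrawn, so all
sites stay biallelic), at most one crossover per gamete (probability r*L,
uniform breakpoint), and multinomial resampling of parents.  An optional hard
sweep multiplies a parent's gamete-sampling weight by (1+s) per copy of the
beneficial allele carried at the sweep site.

Chromosomes are simulated independently; the genome may contain several, so
an empirical-outlier scan has neutral background sequence to calibrate on.
The seed fully determines the output.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .popio import (Genome, HaplotypeMatrix, PopulationMap, write_popmap,
                    write_vcf)

_PURGE_EVERY = 10  # generations between column compactions


@dataclass
class SweepSpec:
    """A single hard sweep planted in one population."""

    population: str = "focal"
    chrom: str = "1"
    position: int = 250_000            # 1-based bp
    s: float = 0.2
    onset_gen: int | None = None       # generations after the split; see below
    require_fixation: bool = True
    min_final_freq: float = 0.9
    max_retries: int = 30


@dataclass
class SimParams:
    """Study conditions for one simulated dataset."""

    n_e: int = 200                     # diploids per population
    chrom_length: int = 500_000        # bp per chromosome
    n_chromosomes: int = 20
    mu: float = 2.5e-7                 # per bp per generation
    r: float = 1e-8                    # per bp per generation
    split_gens: int = 400
    sample_sizes: dict[str, int] = field(
        default_factory=lambda: {"focal": 30, "ref1": 30, "ref2": 30})
    sweep: SweepSpec | None = None
    burn_in_factor: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mu, self.r) < 0:
            raise ValueError("rates must be >= 0")
        if self.n_e < 2 or self.chrom_length < 1 or self.n_chromosomes < 1:
            raise ValueError("n_e, chrom_length and n_chromosomes must be positive")
        if len(self.sample_sizes) != 3:
            raise ValueError("three populations are required")
        for pop, n in self.sample_sizes.items():
            if not 2 <= n <= self.n_e:
                raise ValueError(f"sample size for {pop!r} must be in [2, n_e]")
        sw = self.sweep
        if sw is not None:
            if sw.population not in self.sample_sizes:
                raise ValueError(f"sweep population {sw.population!r} unknown")
            if not 0 <= sw.s <= 1:
                raise ValueError("selection coefficient must lie in [0, 1]")
            if not 1 <= sw.position <= self.chrom_length:
                raise ValueError("sweep position outside [1, chrom_length]")
            if sw.onset_gen is None:
                # Aim fixation shortly before sampling: a conditioned additive
                # sweep takes roughly (2/s) ln(2N) generations; leave twice that.
                est = (2.0 / max(sw.s, 1e-3)) * np.log(2 * self.n_e)
                sw.onset_gen = max(0, int(self.split_gens - 2 * est))
            if not 0 <= sw.onset_gen < self.split_gens:
                raise ValueError("sweep onset must fall within the split phase")

    @property
    def populations(self) -> list[str]:
        return list(self.sample_sizes)

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}


@dataclass
class SweepTruth:
    """Ground truth of the planted sweep, for recovery tests."""

    population: str
    chrom: str
    position: int
    s: float
    onset_gen: int
    final_freq: float                  # beneficial-allele frequency at sampling
    completed: bool                    # final_freq >= min_final_freq
    attempts: int = 1


@dataclass
class SimResult:
    params: SimParams
    genome: Genome                     # all sampled individuals, merged
    popmap: PopulationMap
    truth: SweepTruth | None

    def population_genome(self, population: str) -> Genome:
        samples = self.popmap.samples(population)
        return {c: h.subset_samples(samples) for c, h in self.genome.items()}

    @property
    def samples(self) -> list[str]:
        return list(self.popmap.assignments)


# ---------------------------------------------------------------------------
# Single-population evolution
# ---------------------------------------------------------------------------

class _Pop:
    """Mutable haplotype pool for one population x one chromosome."""

    def __init__(self, n_e: int, length: int, mu: float, r: float,
                 rng: np.random.Generator,
                 positions: np.ndarray | None = None,
                 haplotypes: np.ndarray | None = None,
                 protected: set[int] | None = None):
        self.n = n_e
        self.length = length
        self.mu = mu
        self.r = r
        self.rng = rng
        if positions is None:
            positions = np.empty(0, dtype=np.int64)
            haplotypes = np.empty((2 * n_e, 0), dtype=np.uint8)
        self.pos = positions.copy()
        self.hap = haplotypes.copy()
        self.used = set(int(p) for p in self.pos)
        # positions that stay reserved even after the site is lost here, so a
        # new local mutation can never be conflated with a homologous site in
        # a sibling population (relevant only after the split)
        self.protected = set() if protected is None else set(protected)
        self.used |= self.protected
        self.sweep_col: int | None = None  # column index of the sweep site
        # columns [0, sorted_upto) are position-sorted (restored at each
        # purge); newer mutation columns are appended unsorted past it
        order = np.argsort(self.pos, kind="stable")
        self.pos = self.pos[order]
        self.hap = self.hap[:, order]
        self.sorted_upto = self.pos.size

    # -- per-generation pieces -------------------------------------------

    def _parent_rows(self, fitness: np.ndarray | None
                     ) -> tuple[np.ndarray, np.ndarray]:
        n2 = 2 * self.n
        if fitness is None:
            # uniform parent x uniform haplotype == uniform gamete row
            rows = self.rng.integers(0, n2, size=n2)
            return rows >> 1, rows & 1
        cdf = np.cumsum(fitness)
        parents = np.searchsorted(cdf, self.rng.random(n2) * cdf[-1],
                                  side="right")
        which_hap = self.rng.integers(0, 2, size=n2)
        return parents, which_hap

    def step(self, s: float = 0.0) -> None:
        """Advance one generation; ``s`` > 0 applies genic selection at the
        sweep site ((1+s) fitness factor per beneficial copy)."""
        n2 = 2 * self.n
        fitness = None
        if s > 0.0 and self.sweep_col is not None:
            col = self.hap[:, self.sweep_col].astype(np.float64)
            fitness = (1.0 + s) ** (col[0::2] + col[1::2])
        parents, which_hap = self._parent_rows(fitness)
        rows = 2 * parents + which_hap
        child = self.hap[rows]  # gather copy

        # single-crossover recombination (duplicate gamete draws harmless)
        p_rec = min(self.r * self.length, 1.0)
        n_rec = self.rng.binomial(n2, p_rec)
        if n_rec:
            gametes = self.rng.integers(0, n2, size=n_rec)
            cuts = self.rng.integers(1, self.length + 1, size=n_rec)
            up = self.sorted_upto
            for g, cut in zip(gametes, cuts):
                other = 2 * parents[g] + 1 - which_hap[g]
                k = int(np.searchsorted(self.pos[:up], cut))
                child[g, k:up] = self.hap[other, k:up]
                if up < self.pos.size:
                    mask = self.pos[up:] >= cut
                    child[g, up:][mask] = self.hap[other, up:][mask]

        # mutation (infinite sites: collisions redrawn)
        n_mut = self.rng.poisson(n2 * self.mu * self.length)
        if n_mut:
            new_pos: list[int] = []
            while len(new_pos) < n_mut:
                cands = self.rng.integers(1, self.length + 1,
                                          size=n_mut - len(new_pos))
                for cand in map(int, cands):
                    if cand not in self.used:
                        self.used.add(cand)
                        new_pos.append(cand)
            cols = np.zeros((n2, n_mut), dtype=np.uint8)
            cols[self.rng.integers(0, n2, size=n_mut), np.arange(n_mut)] = 1
            child = np.concatenate([child, cols], axis=1)
            self.pos = np.concatenate([self.pos, np.array(new_pos, dtype=np.int64)])
        self.hap = child

    def purge(self, drop_fixed: bool) -> None:
        counts = self.hap.sum(axis=0, dtype=np.uint16 if self.hap.shape[0] < 65000
                              else np.int64)
        keep = counts > 0
        if drop_fixed:
            keep &= counts < self.hap.shape[0]
        if self.sweep_col is not None:
            keep[self.sweep_col] = True
        for p in self.pos[~keep]:
            if int(p) not in self.protected:
                self.used.discard(int(p))
        idx = np.flatnonzero(keep)
        idx = idx[np.argsort(self.pos[idx], kind="stable")]
        if self.sweep_col is not None:
            sweep_pos = int(self.pos[self.sweep_col])
        self.hap = self.hap[:, idx]
        self.pos = self.pos[idx]
        self.sorted_upto = self.pos.size
        if self.sweep_col is not None:
            self.sweep_col = int(np.searchsorted(self.pos, sweep_pos))

    def add_sweep_allele(self, position: int) -> None:
        """Place the beneficial allele on one random haplotype at ``position``."""
        if position in self.used:
            col = int(np.flatnonzero(self.pos == position)[0])
            # reuse the standing site: put the beneficial label on its derived
            # allele only if monomorphic-ref, else overwrite with a fresh copy
            self.hap[:, col] = 0
        else:
            self.used.add(position)
            self.pos = np.concatenate([self.pos, np.array([position], dtype=np.int64)])
            self.hap = np.concatenate(
                [self.hap, np.zeros((self.hap.shape[0], 1), dtype=np.uint8)], axis=1)
            col = self.hap.shape[1] - 1
        self.hap[int(self.rng.integers(0, self.hap.shape[0])), col] = 1
        self.sweep_col = col

    def sweep_freq(self) -> float:
        if self.sweep_col is None:
            return 0.0
        return float(self.hap[:, self.sweep_col].mean())

    def run(self, generations: int, drop_fixed: bool,
            sweep_s: float = 0.0, sweep_onset: int | None = None,
            sweep_position: int | None = None) -> None:
        for g in range(generations):
            if sweep_onset is not None and g == sweep_onset:
                self.add_sweep_allele(sweep_position)
            self.step(s=sweep_s if self.sweep_col is not None else 0.0)
            if (g + 1) % _PURGE_EVERY == 0 or g == generations - 1:
                self.purge(drop_fixed=drop_fixed)


# ---------------------------------------------------------------------------
# Whole-genome orchestration
# ---------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _split_phase(params: SimParams, chrom_i: int, pop_i: int,
                 anc: _Pop, attempt: int = 0,
                 sweep: SweepSpec | None = None) -> _Pop:
    rng = _rng(params.seed, 2, chrom_i, pop_i, attempt)
    pop = _Pop(params.n_e, params.chrom_length, params.mu, params.r, rng,
               anc.pos, anc.hap, protected=set(map(int, anc.pos)))
    if sweep is None:
        pop.run(params.split_gens, drop_fixed=False)
    else:
        pop.run(params.split_gens, drop_fixed=False, sweep_s=sweep.s,
                sweep_onset=sweep.onset_gen, sweep_position=sweep.position)
    return pop


def simulate(params: SimParams, out_prefix: str | None = None) -> SimResult:
    """Run the full simulation; optionally write VCF/popmap/truth/params files."""
    pops = params.populations
    sweep = params.sweep
    truth: SweepTruth | None = None

    per_pop_chroms: dict[str, list[_Pop]] = {p: [] for p in pops}
    ancestral_sets: list[set[int]] = []
    for ci, chrom in enumerate(params.chrom_names):
        anc = _Pop(params.n_e, params.chrom_length, params.mu, params.r,
                   _rng(params.seed, 1, ci))
        anc.run(params.burn_in_factor * params.n_e, drop_fixed=True)
        ancestral_sets.append(set(map(int, anc.pos)))
        for pi, pop_name in enumerate(pops):
            sw = sweep if (sweep is not None and pop_name == sweep.population
                           and chrom == sweep.chrom) else None
            evolved = _split_phase(params, ci, pi, anc, attempt=0, sweep=sw)
            if sw is not None:
                attempt = 0
                while (sw.require_fixation
                       and evolved.sweep_freq() < sw.min_final_freq
                       and attempt < sw.max_retries):
                    attempt += 1
                    evolved = _split_phase(params, ci, pi, anc,
                                           attempt=attempt, sweep=sw)
                freq = evolved.sweep_freq()
                if sw.require_fixation and freq < sw.min_final_freq:
                    raise RuntimeError(
                        f"sweep allele lost in all {sw.max_retries + 1} attempts")
                truth = SweepTruth(pop_name, chrom, sw.position, sw.s,
                                   sw.onset_gen, freq,
                                   completed=freq >= sw.min_final_freq,
                                   attempts=attempt + 1)
            per_pop_chroms[pop_name].append(evolved)

    genome, popmap = _sample_and_merge(params, per_pop_chroms, ancestral_sets)
    if sum(h.n_sites for h in genome.values()) == 0:
        raise ValueError(
            "zero segregating sites in the sample; increase L*mu*N_e")
    result = SimResult(params, genome, popmap, truth)
    if out_prefix is not None:
        write_outputs(result, out_prefix)
    return result


def _sample_and_merge(params: SimParams,
                      per_pop_chroms: dict[str, list[_Pop]],
                      ancestral_sets: list[set[int]]
                      ) -> tuple[Genome, PopulationMap]:
    """Sample diploids per population and merge the pools into one matrix per
    chromosome.

    Ancestral positions (segregating at the split) denote the same mutation in
    every population and share a union column.  Post-split mutations are
    private; on the rare bp collision between populations the later one is
    shifted by +1 bp (deterministically) to preserve the infinite-sites /
    biallelic contract.  Only sites segregating within the merged sample are
    kept, which is exactly what a VCF of those samples would contain.
    """
    assignments: dict[str, str] = {}
    sampled_rows: dict[str, np.ndarray] = {}
    for pi, pop_name in enumerate(params.populations):
        k = params.sample_sizes[pop_name]
        rng = _rng(params.seed, 3, pi)
        dips = np.sort(rng.choice(params.n_e, size=k, replace=False))
        sampled_rows[pop_name] = np.repeat(2 * dips, 2) + np.tile([0, 1], k)
        for j in range(k):
            assignments[f"{pop_name}{j:03d}"] = pop_name
    labels = [f"{s}_{h}" for s in assignments for h in (1, 2)]

    genome: Genome = {}
    for ci, chrom in enumerate(params.chrom_names):
        anc_set = ancestral_sets[ci]
        claimed: set[int] = set(anc_set)
        blocks: list[tuple[np.ndarray, np.ndarray]] = []
        for pop_name in params.populations:
            p = per_pop_chroms[pop_name][ci]
            pos = p.pos.copy()
            for k, bp in enumerate(map(int, pos)):
                if bp in anc_set:
                    continue  # shared ancestral site: same union column
                q = bp
                while q in claimed:
                    q = q + 1 if q < params.chrom_length else 1
                pos[k] = q
                claimed.add(q)
            blocks.append((pos, p.hap[sampled_rows[pop_name]]))

        union = np.array(sorted(set().union(*[set(map(int, b[0]))
                                              for b in blocks])), dtype=np.int64)
        pos_index = {int(p): i for i, p in enumerate(union)}
        n_rows = sum(len(sampled_rows[p]) for p in params.populations)
        mat = np.zeros((n_rows, union.size), dtype=np.uint8)
        row0 = 0
        for pos, hap in blocks:
            cols = np.array([pos_index[int(x)] for x in pos], dtype=np.int64)
            mat[row0:row0 + hap.shape[0]][:, cols] = hap
            row0 += hap.shape[0]
        counts = mat.sum(axis=0, dtype=np.int64)
        seg = (counts > 0) & (counts < n_rows)
        genome[chrom] = HaplotypeMatrix(chrom, union[seg], mat[:, seg],
                                        list(labels))
    return genome, PopulationMap(assignments)


def write_outputs(result: SimResult, out_prefix: str) -> dict[str, str]:
    """Write VCF, population map, truth BED and a params JSON sidecar."""
    os.makedirs(os.path.dirname(out_prefix) or ".", exist_ok=True)
    paths = {
        "vcf": out_prefix + ".vcf",
        "popmap": out_prefix + ".popmap.txt",
        "params": out_prefix + ".params.json",
    }
    write_vcf(result.genome, result.samples, paths["vcf"],
              chrom_lengths=result.params.chrom_lengths)
    write_popmap(result.popmap, paths["popmap"])
    blob = dataclasses.asdict(result.params)
    with open(paths["params"], "w") as fh:
        json.dump(blob, fh, indent=2, default=str)
    if result.truth is not None:
        paths["truth"] = out_prefix + ".truth.bed"
        t = result.truth
        with open(paths["truth"], "w") as fh:
            fh.write(f"{t.chrom}\t{t.position - 1}\t{t.position}\t"
                     f"sweep_s={t.s};freq={t.final_freq:.4f};"
                     f"completed={int(t.completed)}\n")
    return paths


# ---------------------------------------------------------------------------
# Hand-specified fixtures
# ---------------------------------------------------------------------------

def make_fixtures() -> dict[str, object]:
    """Tiny deterministic datasets for unit tests (hard-coded, not simulated).

    Returns a dict with:
      ``ehh`` -- 4-haplotype, 10-site matrix with known haplotype groups;
      ``fst_pop1``/``fst_pop2`` -- two 10-diploid, 6-site matrices with
      hand-countable allele frequencies;
      ``gtf_text``/``qtl_bed_text`` -- a 3-gene toy GTF and a 5-interval QTL BED.
    """
    # (a) four haplotypes over ten sites; groups split progressively with
    # distance from the central core (site index 4, position 500).
    ehh_alleles = np.array([
        # pos:  100 200 300 400 500 600 700 800 900 1000
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 1, 0, 1],
        [0, 1, 0, 0, 1, 0, 1, 1, 1, 1],
        [1, 1, 0, 0, 1, 0, 1, 1, 1, 0],
    ], dtype=np.uint8)
    ehh = HaplotypeMatrix("1", np.arange(1, 11) * 100, ehh_alleles,
                          ["a_1", "a_2", "b_1", "b_2"])

    # (b) two populations, 10 diploids each, 6 sites; per-site alt counts:
    #   pop1: 8, 20, 10, 0, 5, 1      pop2: 2, 0, 10, 0, 15, 0
    def _col(count: int) -> np.ndarray:
        col = np.zeros(20, dtype=np.uint8)
        col[:count] = 1
        return col

    p1 = np.stack([_col(8), _col(20), _col(10), _col(0), _col(5), _col(1)], axis=1)
    p2 = np.stack([_col(2), _col(0), _col(10), _col(0), _col(15), _col(0)], axis=1)
    positions = np.array([1000, 2000, 3000, 4000, 5000, 6000], dtype=np.int64)
    fst_pop1 = HaplotypeMatrix("1", positions, p1,
                               [f"p1s{i}_{h}" for i in range(10) for h in (1, 2)])
    fst_pop2 = HaplotypeMatrix("1", positions, p2,
                               [f"p2s{i}_{h}" for i in range(10) for h in (1, 2)])

    # (c) three genes on a 100-kb toy chromosome (GTF is 1-based inclusive)
    gtf_lines = [
        # gA, + strand: 5'UTR 1001-1100, CDS 1101-2000 & 3001-3800, 3'UTR 3801-4000
        ("1", "test", "exon", 1001, 2000, "+", "gA", "gA.t1"),
        ("1", "test", "exon", 3001, 4000, "+", "gA", "gA.t1"),
        ("1", "test", "five_prime_utr", 1001, 1100, "+", "gA", "gA.t1"),
        ("1", "test", "CDS", 1101, 2000, "+", "gA", "gA.t1"),
        ("1", "test", "CDS", 3001, 3800, "+", "gA", "gA.t1"),
        ("1", "test", "three_prime_utr", 3801, 4000, "+", "gA", "gA.t1"),
        # gB, - strand, single exon, all CDS
        ("1", "test", "exon", 10001, 12000, "-", "gB", "gB.t1"),
        ("1", "test", "CDS", 10001, 12000, "-", "gB", "gB.t1"),
        # gC, + strand, two transcripts with different exon 2
        ("1", "test", "exon", 20001, 20500, "+", "gC", "gC.t1"),
        ("1", "test", "exon", 21001, 21500, "+", "gC", "gC.t1"),
        ("1", "test", "exon", 20001, 20500, "+", "gC", "gC.t2"),
        ("1", "test", "exon", 22001, 22500, "+", "gC", "gC.t2"),
    ]
    gtf_text = "".join(
        f"{c}\t{src}\t{feat}\t{s}\t{e}\t.\t{strand}\t.\t"
        f'gene_id "{g}"; transcript_id "{t}";\n'
        for c, src, feat, s, e, strand, g, t in gtf_lines)

    qtl_bed_text = (
        "1\t0\t5000\tGrowth_QTL1\t.\n"
        "1\t3500\t15000\tCarcass_QTL1\t.\n"
        "1\t15000\t20000\tMeat_QTL1\t.\n"
        "1\t50000\t60000\tGrowth_QTL2\t.\n"
        "1\t95000\t100000\tHealth_QTL1\t.\n")

    return {"ehh": ehh, "fst_pop1": fst_pop1, "fst_pop2": fst_pop2,
            "gtf_text": gtf_text, "qtl_bed_text": qtl_bed_text}


def write_fixtures(out_dir: str) -> dict[str, str]:
    """Materialize :func:`make_fixtures` as plain-text files."""
    os.makedirs(out_dir, exist_ok=True)
    fx = make_fixtures()
    paths = {}
    paths["gtf"] = os.path.join(out_dir, "toy_genes.gtf")
    with open(paths["gtf"], "w") as fh:
        fh.write(fx["gtf_text"])
    paths["qtl"] = os.path.join(out_dir, "toy_qtl.bed")
    with open(paths["qtl"], "w") as fh:
        fh.write(fx["qtl_bed_text"])
    ehh: HaplotypeMatrix = fx["ehh"]
    paths["ehh_vcf"] = os.path.join(out_dir, "toy_ehh.vcf")
    write_vcf({"1": ehh}, ehh.sample_names, paths["ehh_vcf"],
              chrom_lengths={"1": 1000})
    return paths
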