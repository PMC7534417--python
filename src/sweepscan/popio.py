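"""Readers/writers and shared genomic containers for the scan pipeline.

All internal coordinates are 0-based half-open.  The two 1-based external
conventions (VCF POS, GTF start/end inclusive) are converted exactly once, at
parse time.  ``HaplotypeMatrix.positions`` keeps the 1-based VCF POS values
because every statistic reports positions in VCF convention; window assignment
converts with ``pos - 1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("sweepscan")

#: Chromosome names treated as autosomes by default (pig: 18 autosomes + X).
DEFAULT_AUTOSOMES = tuple(str(i) for i in range(1, 19))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeMatrix:
    """Phased binary allele matrix for one chromosome.

    ``alleles`` is H x S over {0, 1} with H haplotypes (two per diploid, row
    2k and 2k+1 belong to sample k) and S sites; 0 is the reference allele.
    ``positions`` are 1-based physical bp, strictly increasing.
    """

    chrom: str
    positions: np.ndarray          # (S,) int64, 1-based, strictly increasing
    alleles: np.ndarray            # (H, S) uint8 in {0,1}
    haplotype_labels: list[str]    # "sample_hapidx", two per diploid
    phased: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.alleles.shape[1] != self.positions.size:
            raise ValueError("positions/alleles size mismatch")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"{self.chrom}: positions not strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be binary")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def sample_names(self) -> list[str]:
        return [lab.rsplit("_", 1)[0] for lab in self.haplotype_labels[::2]]

    def require_phased(self) -> None:
        if not self.phased:
            raise ValueError(
                f"{self.chrom}: haplotype data are unphased; EHH-type "
                "statistics require phased haplotypes"
            )

    def subset_samples(self, samples: list[str]) -> "HaplotypeMatrix":
        """Rows restricted to the given diploid samples, order preserved."""
        index = {s: i for i, s in enumerate(self.sample_names)}
        rows: list[int] = []
        labels: list[str] = []
        for s in samples:
            if s not in index:
                raise KeyError(f"sample {s!r} not in haplotype matrix")
            i = index[s]
            rows += [2 * i, 2 * i + 1]
            labels += [self.haplotype_labels[2 * i], self.haplotype_labels[2 * i + 1]]
        return HaplotypeMatrix(self.chrom, self.positions.copy(),
                               self.alleles[rows], labels, self.phased)

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.chrom, self.positions[idx],
                               self.alleles[:, idx], list(self.haplotype_labels),
                               self.phased)


#: A genome is an ordered mapping chromosome -> HaplotypeMatrix.
Genome = dict[str, HaplotypeMatrix]


@dataclass
class PopulationMap:
    """sample id -> population label; each sample exactly once."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.assignments)) != len(self.assignments):
            raise ValueError("duplicate sample in population map")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p)
        return list(seen)

    def samples(self, population: str) -> list[str]:
        out = [s for s, p in self.assignments.items() if p == population]
        if not out:
            raise KeyError(f"population {population!r} has no samples")
        return out


@dataclass
class WindowGrid:
    """Non-overlapping half-open windows tiling each chromosome."""

    chrom_lengths: dict[str, int]
    window_size: int = 100_000
    windows: pd.DataFrame = field(init=False)  # chrom, start, end

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        rows = []
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            n = math.ceil(length / self.window_size)
            for i in range(n):
                rows.append((chrom, i * self.window_size,
                             min((i + 1) * self.window_size, length)))
        self.windows = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def window_index(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Row index in ``self.windows`` for 1-based positions on ``chrom``."""
        pos0 = np.asarray(positions, dtype=np.int64) - 1
        length = self.chrom_lengths[chrom]
        if pos0.size and (pos0.min() < 0 or pos0.max() >= length):
            raise ValueError(f"position outside chromosome {chrom}")
        first = int(self.windows.index[self.windows["chrom"] == chrom][0])
        return first + pos0 // self.window_size


def make_windows(chrom_lengths: dict[str, int], window_size: int = 100_000) -> WindowGrid:
    return WindowGrid(dict(chrom_lengths), window_size)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]            # 0-based half-open, sorted
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


@dataclass
class FeatureSet:
    """Gene models: gene -> transcripts -> exon/CDS/UTR intervals."""

    transcripts: list[Transcript]

    def on_chrom(self, chrom: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.chrom == chrom]

    @property
    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.transcripts:
            seen.setdefault(t.gene_id)
        return list(seen)


@dataclass
class IntervalSet:
    """Named genomic intervals (QTL, candidate regions, ...), 0-based half-open."""

    intervals: pd.DataFrame  # chrom, start, end, name[, score]

    def __post_init__(self) -> None:
        df = self.intervals
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"empty/negative interval {bad['chrom']}:{bad['start']}-{bad['end']}")

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, region: str | None = None,
             genotype_only: bool = False) -> tuple[Genome, list[str]]:
    """Read biallelic SNVs with GT into per-chromosome haplotype matrices.

    Multiallelic and non-SNV records are skipped (count logged); sites with
    any missing call are dropped (count logged).  Unless ``genotype_only`` is
    set, every genotype must be phased.  Returns (genome, sample names).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples / no GT field")
    if region is not None:
        contig = region.split(":")[0]
        if contig not in set(vcf.seqnames):
            raise ValueError(f"region contig {contig!r} not in VCF header contigs")

    per_chrom: dict[str, tuple[list[int], list[np.ndarray]]] = {}
    n_skipped_allelic = n_skipped_missing = n_unphased = 0
    phased_out = not genotype_only
    for var in (vcf(region) if region else vcf):
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped_allelic += 1
            continue
        gts = np.asarray(var.genotype.array())  # (n, 3): a, b, phased flag
        if (gts[:, :2] < 0).any():
            n_skipped_missing += 1
            continue
        if not genotype_only and not gts[:, 2].all():
            n_unphased += 1
            continue
        col = gts[:, :2].astype(np.uint8).reshape(-1)
        pos_list, col_list = per_chrom.setdefault(var.CHROM, ([], []))
        pos_list.append(var.POS)
        col_list.append(col)
    if n_skipped_allelic:
        log.info("read_vcf: skipped %d multiallelic/non-SNV records", n_skipped_allelic)
    if n_skipped_missing:
        log.info("read_vcf: dropped %d sites with missing genotypes", n_skipped_missing)
    if n_unphased:
        log.info("read_vcf: dropped %d unphased sites (use genotype_only to keep)",
                 n_unphased)

    genome: Genome = {}
    labels = [f"{s}_{h}" for s in samples for h in (1, 2)]
    for chrom, (pos_list, col_list) in per_chrom.items():
        genome[chrom] = HaplotypeMatrix(
            chrom, np.array(pos_list, dtype=np.int64),
            np.stack(col_list, axis=1) if col_list else np.empty((len(labels), 0), np.uint8),
            list(labels), phased=phased_out)
    if not genome:
        raise ValueError(
            f"{path}: zero sites retained (filters: biallelic SNV, complete GT"
            + ("" if genotype_only else ", phased") + ")")
    return genome, samples


def vcf_chrom_lengths(path: str) -> dict[str, int]:
    """Contig lengths from the VCF header."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    return {name: int(length) for name, length in zip(vcf.seqnames, vcf.seqlens)}


def write_vcf(genome: Genome, samples: list[str], path: str,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write phased biallelic SNVs (REF=A, ALT=C placeholders) as VCF 4.2 text."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for chrom, hap in genome.items():
            length = (chrom_lengths or {}).get(
                chrom, int(hap.positions[-1]) if hap.n_sites else 1)
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, hap in genome.items():
            a = hap.alleles
            sep = "|" if hap.phased else "/"
            for j in range(hap.n_sites):
                gts = "\t".join(f"{a[2 * i, j]}{sep}{a[2 * i + 1, j]}"
                                for i in range(len(samples)))
                fh.write(f"{chrom}\t{hap.positions[j]}\t.\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_popmap(path: str) -> PopulationMap:
    """Two-column sample<TAB>population plain-text file."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>population'")
            if parts[0] in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample {parts[0]!r}")
            assignments[parts[0]] = parts[1]
    return PopulationMap(assignments)


def write_popmap(popmap: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.assignments.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def site_maf(hap: HaplotypeMatrix) -> np.ndarray:
    alt = hap.alleles.sum(axis=0, dtype=np.int64)
    freq = alt / hap.n_haplotypes
    return np.minimum(freq, 1.0 - freq)


def filter_maf(hap: HaplotypeMatrix, maf_min: float) -> HaplotypeMatrix:
    """Keep sites with minor allele frequency strictly greater than ``maf_min``,
    computed over all haplotypes in the matrix."""
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    return hap.take_sites(np.flatnonzero(site_maf(hap) > maf_min))


def filter_maf_genome(genome: Genome, maf_min: float) -> Genome:
    return {c: filter_maf(h, maf_min) for c, h in genome.items()}


# ---------------------------------------------------------------------------
# GTF / BED
# ---------------------------------------------------------------------------

def _gtf_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


_FEATURE_SLOTS = {"exon": "exons", "CDS": "cds",
                  "five_prime_utr": "utr5", "three_prime_utr": "utr3",
                  "5UTR": "utr5", "3UTR": "utr3"}


def read_gtf(path: str) -> FeatureSet:
    """Parse gene models from GTF (1-based inclusive -> 0-based half-open)."""
    transcripts: dict[str, Transcript] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _, feature, start, end, _, strand, _, attr_field = fields
            if feature not in _FEATURE_SLOTS:
                continue
            try:
                iv = (int(start) - 1, int(end))  # 1-based inclusive -> half-open
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            attrs = _gtf_attributes(attr_field)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise ValueError(f"{path}:{lineno}: missing gene_id/transcript_id")
            tid = attrs["transcript_id"]
            tr = transcripts.setdefault(
                tid, Transcript(tid, attrs["gene_id"], chrom, strand, []))
            getattr(tr, _FEATURE_SLOTS[feature]).append(iv)
    for tr in transcripts.values():
        for slot in ("exons", "cds", "utr5", "utr3"):
            getattr(tr, slot).sort()
        if not tr.exons:
            raise ValueError(f"transcript {tr.transcript_id} has no exons")
    return FeatureSet(list(transcripts.values()))


def read_bed(path: str) -> IntervalSet:
    """BED4+ (0-based half-open) -> IntervalSet."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            score = fields[4] if len(fields) > 4 else "."
            rows.append((fields[0], start, end, name, score))
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                   "name", "score"]))


def write_bed(intervals: IntervalSet | pd.DataFrame, path: str) -> None:
    """Sorted, tab-separated BED; column 4 carries the name/method-support."""
    df = intervals.intervals if isinstance(intervals, IntervalSet) else intervals
    df = df.sort_values(["chrom", "start", "end"])
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fields = [str(row.chrom), str(int(row.start)), str(int(row.end))]
            if hasattr(row, "name"):
                fields.append(str(row.name))
            if hasattr(row, "score"):
                fields.append(str(row.score))
            fh.write("\t".join(fields) + "\n")
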