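"""Positional SNV annotation and region/gene/QTL overlap reporting.

Each SNV receives exactly one of eight positional categories against the gene
models, by precedence

    exonic = splicing > UTR5/UTR3 > intronic > upstream/downstream > intergenic

evaluated across all overlapping transcripts (the highest-precedence category
over any transcript wins; the exonic/splicing tie breaks to exonic, the
upstream/downstream tie to upstream).  "Splicing" means an intronic position
within ``splice_bp`` of an exon boundary; upstream/downstream extend
``upstream_bp`` from the transcript span on the strand-correct side.  Exonic
sub-classes (synonymous etc.) require a reference sequence and are out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popio import FeatureSet, IntervalSet, Transcript

CATEGORIES = ("exonic", "splicing", "UTR5", "UTR3", "intronic",
              "upstream", "downstream", "intergenic")
#: precedence rank (lower wins); order within CATEGORIES breaks ties
_RANK = {"exonic": 0, "splicing": 0, "UTR5": 1, "UTR3": 1, "intronic": 2,
         "upstream": 3, "downstream": 3, "intergenic": 4}

DEFAULT_UPSTREAM_BP = 1_000
DEFAULT_SPLICE_BP = 2


@dataclass
class SnvAnnotation:
    chrom: str
    pos: int                          # 1-based
    category: str
    genes: tuple[str, ...]            # nearest gene for intergenic


def _in_any(p0: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= p0 < e for s, e in intervals)


def _transcript_category(p0: int, tr: Transcript, upstream_bp: int,
                         splice_bp: int) -> str | None:
    """Category of a 0-based position w.r.t. one transcript, or None."""
    if tr.start <= p0 < tr.end:
        if _in_any(p0, tr.exons):
            if tr.cds and _in_any(p0, tr.cds):
                return "exonic"
            if tr.utr5 and _in_any(p0, tr.utr5):
                return "UTR5"
            if tr.utr3 and _in_any(p0, tr.utr3):
                return "UTR3"
            return "exonic"
        # intronic; splicing if within splice_bp of an exon boundary
        for (s, e) in tr.exons:
            if e <= p0 < e + splice_bp or s - splice_bp <= p0 < s:
                return "splicing"
        return "intronic"
    if tr.strand == "+":
        if tr.start - upstream_bp <= p0 < tr.start:
            return "upstream"
        if tr.end <= p0 < tr.end + upstream_bp:
            return "downstream"
    else:
        if tr.end <= p0 < tr.end + upstream_bp:
            return "upstream"
        if tr.start - upstream_bp <= p0 < tr.start:
            return "downstream"
    return None


def classify_snv(chrom: str, pos: int, features: FeatureSet,
                 upstream_bp: int = DEFAULT_UPSTREAM_BP,
                 splice_bp: int = DEFAULT_SPLICE_BP) -> SnvAnnotation:
    """Assign the single positional category for a 1-based SNV position."""
    p0 = pos - 1
    best: str | None = None
    genes: set[str] = set()
    for tr in features.on_chrom(chrom):
        cat = _transcript_category(p0, tr, upstream_bp, splice_bp)
        if cat is None:
            continue
        if best is None or _beats(cat, best):
            best, genes = cat, {tr.gene_id}
        elif cat == best:
            genes.add(tr.gene_id)
    if best is None:
        nearest = _nearest_gene(p0, features.on_chrom(chrom))
        return SnvAnnotation(chrom, pos, "intergenic",
                             (nearest,) if nearest else ())
    return SnvAnnotation(chrom, pos, best, tuple(sorted(genes)))


def _beats(a: str, b: str) -> bool:
    if _RANK[a] != _RANK[b]:
        return _RANK[a] < _RANK[b]
    return CATEGORIES.index(a) < CATEGORIES.index(b)


def _nearest_gene(p0: int, transcripts: list[Transcript]) -> str | None:
    best_gene, best_d = None, None
    for tr in transcripts:
        d = max(tr.start - p0, p0 - (tr.end - 1), 0)
        if best_d is None or d < best_d:
            best_gene, best_d = tr.gene_id, d
    return best_gene


def classify_snvs(sites: pd.DataFrame, features: FeatureSet,
                  upstream_bp: int = DEFAULT_UPSTREAM_BP,
                  splice_bp: int = DEFAULT_SPLICE_BP) -> pd.DataFrame:
    """Vector form over a DataFrame with chrom/pos columns."""
    anns = [classify_snv(str(r.chrom), int(r.pos), features,
                         upstream_bp, splice_bp)
            for r in sites.itertuples(index=False)]
    out = sites[["chrom", "pos"]].copy()
    out["category"] = [a.category for a in anns]
    out["genes"] = [";".join(a.genes) for a in anns]
    return out


def category_tally(annotations: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions per category; fractions are NaN on empty input."""
    counts = {c: int((annotations["category"] == c).sum()) for c in CATEGORIES}
    total = sum(counts.values())
    fracs = {c: (counts[c] / total if total else np.nan) for c in CATEGORIES}
    return pd.DataFrame({"category": list(CATEGORIES),
                         "count": [counts[c] for c in CATEGORIES],
                         "fraction": [fracs[c] for c in CATEGORIES]})


# ---------------------------------------------------------------------------
# Region overlaps
# ---------------------------------------------------------------------------

def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Half-open interval intersection length (0 when touching)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def region_gene_overlaps(regions: IntervalSet, features: FeatureSet
                         ) -> pd.DataFrame:
    """Any-bp overlap of candidate regions with gene spans (union over a
    gene's transcripts); one row per (region, gene)."""
    spans: dict[str, tuple[str, int, int]] = {}
    for tr in features.transcripts:
        g = spans.get(tr.gene_id)
        if g is None:
            spans[tr.gene_id] = (tr.chrom, tr.start, tr.end)
        else:
            spans[tr.gene_id] = (g[0], min(g[1], tr.start), max(g[2], tr.end))
    rows = []
    for r in regions.intervals.itertuples(index=False):
        for gene, (chrom, s, e) in spans.items():
            if chrom != r.chrom:
                continue
            ov = _overlap(int(r.start), int(r.end), s, e)
            if ov > 0:
                rows.append((r.chrom, int(r.start), int(r.end), r.name,
                             gene, ov))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region",
                                       "gene", "overlap_bp"])


def region_qtl_overlaps(regions: IntervalSet, qtl: IntervalSet,
                        trait_class=lambda name: name.split("_")[0]
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overlapping QTL per region (with overlap length) and aggregate QTL
    counts per trait class; the class of a QTL derives from its name."""
    rows = []
    for r in regions.intervals.itertuples(index=False):
        for q in qtl.intervals.itertuples(index=False):
            if q.chrom != r.chrom:
                continue
            ov = _overlap(int(r.start), int(r.end), int(q.start), int(q.end))
            if ov > 0:
                rows.append((r.chrom, int(r.start), int(r.end), r.name,
                             q.name, trait_class(str(q.name)), ov))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "region",
                                        "qtl", "trait_class", "overlap_bp"])
    if len(table):
        agg = (table.drop_duplicates("qtl").groupby("trait_class")
               .size().rename("n_qtl").reset_index())
    else:
        agg = pd.DataFrame(columns=["trait_class", "n_qtl"])
    return table, agg
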