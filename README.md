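# sweepscan

Selection-signature scanning for resequenced populations: find genomic
regions under recent positive selection in a **focal** population by
contrasting it with two diverged **reference** populations, then annotate
the candidate regions against gene models and QTL intervals.

The pipeline is aimed at livestock-style designs (e.g. a commercial pig
breed scanned against two unimproved breeds) but is agnostic to organism:
it consumes a phased multi-sample VCF of biallelic SNVs, a two-column
sample→population map, and optionally a GTF of gene models and a BED of
QTL. A forward Wright–Fisher simulator with a plantable hard sweep
generates truth-known data so the whole pipeline can be validated without
any external dataset.

## The three statistics

For every SNV (after a MAF > 0.01 filter) and in non-overlapping 100-kb
windows:

* **d_i** — pairwise Weir–Cockerham F_ST between the focal population i and
  each reference j, z-standardized with genome-wide (autosomal) constants
  and summed: `d_i = Σ_j (F_ST^ij − E[F_ST^ij]) / sd[F_ST^ij]`. Window
  value = mean over SNVs. High values mark focal-lineage-specific
  differentiation.
* **iHH12** — the area under the EHH12 decay curve around each core SNV,
  where EHH12 pools the two largest haplotype classes
  (`[C(n1+n2,2) + Σ_{k≥3} C(nk,2)] / C(H,2)`), integrated against physical
  distance until EHH12 < 0.05, then z-normalized genome-wide. Elevated
  values mark long shared haplotypes.
* **CLR** — a composite likelihood ratio computed every 1 kb comparing a
  star-like sweep model (lineages escape a sweep at distance d with
  probability 1 − e^{−αd}; background SFS distorted accordingly) against
  the genome-wide background SFS, maximized over α. Window value = max.

Each statistic flags the empirical 5% right tail of its window
distribution; windows flagged by **at least two** statistics become
consensus candidate regions (adjacent windows merged), which are then
intersected with genes and QTL. See `docs/methods.md` for the full model
descriptions, numerical conventions and limitations.

## Worked example

Simulate eight 300-kb chromosomes for three populations (N_e = 100,
split 200 generations ago, 20 diploids sampled each) with a hard sweep
(s = 0.3) at position 150,000 of chromosome 1, then scan:

```bash
sweepscan simulate --out-prefix sim --seed 42 --n-e 100 \
    --chrom-length 300000 --n-chromosomes 8 --split-gens 200 \
    --samples 20,20,20 --sweep --sweep-s 0.3
# wrote sim.vcf (2522 segregating sites)
# sweep on chr1:150000 final freq 1.000 (completed=True)

sweepscan full-scan --vcf sim.vcf --popmap sim.popmap.txt --out-dir scan \
    --window-size 20000 --min-sites 5 --autosomes all --edge-ok
# 2 consensus regions (3 windows)

cat scan/consensus.regions.bed
# 1    120000  140000  clr,ihh12   1
# 1    180000  220000  di,ihh12    2
```

Both consensus regions sit on the swept chromosome, flanking the planted
site at 150 kb — under these parameters the hitchhiking footprint spans
the whole chromosome, so any of its windows can carry the peak (see the
limitations section of `docs/methods.md`). `scan/` also contains per-site
and per-window TSV tracks for each statistic, the per-method flagged-window
BEDs, a Venn-count JSON (here: d_i 1, CLR 5, iHH12 3 exclusive windows;
d_i∩iHH12 2, CLR∩iHH12 1), and `config.used.json` recording every resolved
parameter plus the three empirical thresholds (d_i 1.91, CLR 8.67,
iHH12 2.07 for this run).

With gene models and QTL, add `--gtf genes.gtf --qtl-bed qtl.bed` to get
region→gene and region→QTL overlap tables, or run the `annotate`
subcommand on any regions BED. The `fst-di`, `ihh12`, `clr` and
`consensus` subcommands run individual stages; everything is also callable
as a library (`sweepscan.full_scan`, `sweepscan.simulate`, ...).

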