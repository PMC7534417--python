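# Methods

`sweepscan` detects candidate selective sweeps in a focal population by
combining three signals that respond to different footprints of recent
positive selection — allele-frequency differentiation, extended haplotype
homozygosity, and site-frequency-spectrum distortion — and keeping only
genomic windows supported by at least two of them. A forward Wright–Fisher
simulator with a plantable hard sweep supplies truth-known data, so every
stage of the pipeline is testable without external downloads.

## Scan statistics

### d_i (locus-specific differentiation)

For each SNV, pairwise F_ST between the focal population i and each
reference j is estimated with the Weir & Cockerham (1984) single-locus
variance-components estimator θ̂ = a/(a+b+c), computed from diploid sample
sizes, allele frequencies and observed heterozygosities. Negative estimates
are retained (clamping would bias the moments below). A Hudson-style
estimator is available as a sensitivity switch.

Per-SNV values are standardized and summed over references:

    d_i = Σ_j ( F_ST^{ij} − E[F_ST^{ij}] ) / sd[F_ST^{ij}]

where E and sd are the mean and *population* standard deviation (ddof = 0,
so each addend has exactly unit variance) over all autosomal SNVs. By
default "autosomes" means chromosomes named "1".."18" (the pig karyotype
this pipeline is aimed at); any other chromosome set can be passed
explicitly. X-linked sites receive d_i computed with autosomal constants
but are excluded from threshold calibration.

### iHH12 (integrated pooled haplotype homozygosity)

EHH12 at flanking site x is the probability that two random haplotypes are
identical over the closed site interval [core..x], after pooling the two
largest haplotype classes:

    EHH12 = [ C(n1+n2, 2) + Σ_{k≥3} C(n_k, 2) ] / C(H, 2).

Pooling keeps power when a sweep carries two frequent haplotypes. At the
core itself the partition is by core allele, so EHH12 starts at exactly 1.
Raw iHH12 is the trapezoidal integral of the decay curve against physical
distance in bp (a uniform recombination map is assumed; no genetic map is
used), extended marker by marker in both directions until EHH12 < 0.05
(configurable), with the final trapezoid cut at the interpolated crossing.
A core is marked missing when a direction reaches the chromosome edge or an
inter-marker gap > 200 kb before the cutoff; the integral is truncated at
1 Mb (`max_extend`) regardless. An `edge_ok` switch instead truncates the
integral at the edge, the standard practice for contigs short relative to
the homozygosity decay length (the simulated 500-kb chromosomes are; real
pig chromosomes are not, so the switch is off by default).

Raw values are z-normalized in a single genome-wide pool (no
derived-allele-frequency bins): iHH12* = (iHH12 − E[iHH12]) / sd[iHH12],
with the population-sd convention. The per-window summary is the mean of
normalized values (a max switch exists).

The whole-chromosome walk is compiled with numba; the pure-Python
marker-by-marker walk is retained and the test suite asserts the two agree
site-by-site on random instances.

### CLR (composite likelihood ratio)

The background model is the genome-wide SFS: p_j = P(derived count j) in a
sample of n haplotypes, estimated empirically with optional add-one
smoothing. The sweep model is a star-like approximation: a lineage at
distance d from the proposed sweep site fails to escape with probability
exp(−α·d); the k swept lineages coalesce into one representative, the
pre-sweep configuration of the remaining m = n−k+1 lineages is drawn from
the background spectrum projected to size m by hypergeometric downsampling,
and the representative's allele is copied to its k descendants.
Marginalizing k ~ Binomial(n, e^{−αd}) gives P(j | α, d).

    CLR(x) = 2 [ max_α Σ_i log P(j_i | α, d_i) − Σ_i log p_{j_i} ]

maximized over a logarithmic α grid (13 points, 1e−7..1e−2 per bp, plus
α = 0, which is defined to be the background model, so CLR ≥ 0 and ties go
to the smaller α). Test positions are every 1 kb; sites within ±200 kb
contribute (beyond that P ≈ background). Per-window value is the max over
grid points.

Two ascertainment modes:

* **polymorphic** — input counts are 1..n−1 and model probabilities are
  renormalized to those classes. Appropriate when sites were ascertained as
  polymorphic *within the scanned sample*.
* **full-class** (scan default) — counts 0 and n are included as data. This
  is the right mode for a multi-population VCF: a site polymorphic in the
  union of populations but fixed (or lost) in the focal sample is exactly
  the footprint a sweep leaves, and conditioning it away removes most of
  the signal (the analogue of including substitutions/invariant sites in a
  CLR scan). Both modes use the same kernel;
  the unfolded spectrum uses the simulator's known ancestral allele, and a
  folded mode exists for unpolarized data.

The genome scan evaluates P(j | α·d) from a 4096-node geometric table in
u = α·d (relative node spacing ≈ 0.6%, u clamped to [1e−9, 40]) with linear
interpolation; α = 0 is always evaluated exactly, so CLR ≥ 0 survives
tabulation. `clr_at` is exact (no table) and is what the oracle tests
check; table and exact evaluations agree to ~1e−4 in log likelihood.

## Windows, thresholds, consensus

All statistics share non-overlapping half-open windows (default 100 kb;
terminal windows shorter). A window needs ≥ 10 contributing sites, else it
is missing (never zero). The threshold for each statistic is the empirical
(1 − tail) quantile of type "higher" — the smallest observed value with at
least (1 − tail) of the mass at or below it — over defined windows;
flagging is strictly-greater-than, so the flagged fraction never exceeds
the tail (exactly 5 of 100 distinct values at tail 0.05). At least
⌈1/tail⌉ defined windows are required for the quantile to be meaningful.

Consensus keeps windows flagged by ≥ 2 of the three statistics; maximal
runs of coordinate-adjacent kept windows merge into candidate regions
(missing or unflagged windows break runs), carrying the union of supports
and per-method peak values. Venn counts over the seven exclusive support
classes are reported at window or merged-region level.

## Annotation

Each SNV gets exactly one positional category by precedence
exonic = splicing > UTR5/UTR3 > intronic > upstream/downstream > intergenic,
evaluated over all overlapping transcripts; the exonic/splicing tie breaks
to exonic and upstream/downstream to upstream. Splicing means an intronic
position within 2 bp of an exon boundary; upstream/downstream extend
1,000 bp from the transcript span on the strand-correct side (both
distances configurable; they mirror common annotation-tool defaults).
Exonic sub-classes (synonymous/nonsynonymous/stop) need a reference
sequence and codon logic and are out of scope. Region overlap with genes
and QTL uses half-open interval intersection — touching intervals do not
overlap — and QTL are aggregated per trait class parsed from their names.

## Synthetic data

The simulator is a discrete-generation forward Wright–Fisher model: an
ancestral population of N_e diploids evolves 10·N_e burn-in generations
from a monomorphic start (approximate mutation–drift equilibrium at these
scales), then splits into one focal and two reference populations that
evolve in isolation for `split_gens` generations. Each generation applies
Poisson(2N·μ·L) mutations under an infinite-sites rule (collisions
redrawn, so sites stay biallelic), at most one crossover per gamete
(probability r·L, uniform breakpoint; valid while r·L ≪ 1), and
multinomial parent resampling. A configured sweep places one beneficial
copy at a fixed position at the onset generation and multiplies a parent's
gamete-sampling weight by (1+s) per copy. With `require_fixation`, a
replicate whose beneficial allele ends below 0.9 frequency re-runs the
focal population's post-split phase on that chromosome with a seed derived
from (seed, attempt), up to a retry cap — burn-in and the other
populations are unaffected by the sweep, so only that phase needs
re-running. The default onset, split_gens − 2·(2/s)·ln(2N), aims fixation
shortly before sampling, the regime haplotype statistics are powered for.

Chromosomes are independent replicates of this process; the genome may
contain many, which an empirical-outlier scan needs as neutral background.
Sampling takes the requested diploids without replacement; only sites
segregating in the merged sample are emitted (exactly what a VCF of those
samples contains), with allele 0 the ancestral state. The same seed yields
byte-identical VCF output.

What the simulator does *not* emulate: migration or post-split gene flow,
demographic change, soft sweeps from recurrent mutation, variable
recombination/mutation maps, genotyping error or missingness, and the
ascertainment quirks of real resequencing. Passing recovery tests on these
data show the pipeline's statistics respond to a textbook hard sweep under
drift and divergence — not that the pipeline's power on livestock
resequencing data matches any particular study.

## Problem sizes and validation conditions

The end-to-end recovery study uses three populations of N_e = 200, twenty
independent 500-kb chromosomes (10 Mb; 100 windows of 100 kb),
μ = 2.5e−7, r = 1e−8, a 400-generation split, 30/30/30 sampled diploids,
and a hard sweep s = 0.2 at the midpoint of chromosome 1 with fixation
enforced; 20 seeds per arm in the test suite (8 per arm in the acceptance
script). Each replicate simulates in ~12 s and scans in ~3 s on one core.
The scan applies the MAF > 0.01 site filter (computed over all haplotypes
of the combined sample), 5% tails, two-method consensus, and `edge_ok`
iHH12 (the chromosomes are shorter than the homozygosity decay length).

## Known limitations

* **Sweep-footprint scale.** At s = 0.2 and r = 1e−8 the expected
  hitchhiking footprint, roughly s/(r·ln 2N_e s) ≈ 4.5 Mb, is nine times a
  simulated chromosome: a completed sweep affects *every* window of its
  chromosome nearly uniformly (measured focal-fixed-site counts per 100-kb
  window on a swept chromosome: 24/28/20/40/42 — no central peak). The
  window *containing the site* is therefore statistically exchangeable with
  its chromosome neighbours, and single-window localization of the sweep
  site is not achievable in this parameter regime by any of the three
  statistics; localization would require a footprint well below the
  chromosome length (r larger by ~50×, or much weaker selection). Window-
  level false-positive calibration (the 5% tails, neutral consensus rate)
  is unaffected and holds.
* **Drift noise.** With N_e = 200 and a 400-generation split, between-window
  genealogical variance among neutral windows is comparable to the swept
  chromosome's elevation in d_i/CLR/iHH12, so even chromosome-level
  ranking of the swept chromosome is unreliable at these scales.
* **MAF filtering and iHH12.** The MAF > 0.01 filter over the combined
  sample removes combined-sample singletons; immediately after fixation the
  focal population's new variation is mostly such singletons, which slows
  the observable EHH12 decay around a swept site.
* The annotation stage classifies "exonic" without coding-effect
  sub-classes, and enrichment analysis is out of scope.
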