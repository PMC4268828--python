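# nucleodyn

Differential nucleosome occupancy, repositioning and viewpoint-contact
analysis for MNase-seq time courses.

When cells respond to a stimulus such as TNFα, nucleosomes reposition within
minutes — locally (single dyads sliding tens of base pairs) and at scale
(kilobase- to megabase-wide domains losing or gaining occupancy). `nucleodyn`
is a library + CLI for quantifying both from paired-end mononucleosome
sequencing, and for relating the resulting depleted domains to transcription
factor binding, gene expression classes and chromosome conformation (3C/4C)
contacts. It ships a seeded synthetic-data generator with planted ground
truth, so every statistical guarantee the pipeline makes is tested.

## The statistic

The genome is tiled with non-overlapping windows *w₁ … wₙ* of constant size
(5 kbp by default). With fragment-midpoint counts *rᵢ* (time t₁) and *sᵢ*
(time t₂) per window, each window receives a depth-normalized log-ratio

```
qᵢ = log₂( (rᵢ + c) / (s̃ᵢ + c) ),   s̃ᵢ = sᵢ · R/S,
```

where *R*, *S* are the library totals and *c* = 0.5 a pseudocount. The set
*Q* is centred by its mean over scored windows, ‖qᵢ‖ = qᵢ − Q̄, so that
‖qᵢ‖ measures a window's change relative to the genome-wide trend.
Windows inside *transcriptionally inert* regions — no expressed gene,
negligible RNA signal — can only fluctuate stochastically; their centred
values form an empirical null with cumulative distribution *N*. A window is
called **depleted** at t₂ when its right-tail empirical p-value
p = (1 + #{null ≥ ‖qᵢ‖}) / (1 + m) survives Benjamini–Hochberg at α = 0.05
(enrichment is the symmetric left tail). Because the t₂ counts are rescaled
to the t₁ depth before anything else, multiplying either library by a
constant changes no centred value, p-value or label — exactly.

Around this core the package provides:

- **multi-scale domains** — the same statistic at 5/25/50/100 kbp windows;
- **dyad repositioning** — Gaussian-kernel midpoint density, greedy dyad
  calls with 147-bp exclusion, mutual-nearest-neighbour matching between
  time points, and the ">10 bp" repositioning criterion;
- **metagenes** — gene bodies cut into 50-bp windows, rescaled onto 100
  bins between TSS and TTS with 5-kbp absolute flanks, summed per
  expression class (up / down / constitutive, classified by >±0.6 or ±0.01
  log₂ fold-change with >100 reads per gene);
- **peak embedding & association** — peaks embedded in depleted windows at
  ≥25 % of their length; Fisher's exact test (exact integer arithmetic for
  small tables), promoter/intragenic/intergenic annotation, IUPAC consensus
  scanning (e.g. the NF-κB motif `GGRRNNYYCC`) on both strands;
- **contact domainogram** — binary 3C-seq signal per restriction-fragment
  end, enrichment in 2–200 kbp sliding windows over a 3,000-end sampled
  background, permutation-calibrated threshold at FDR < 0.01.

## Worked example

Run the bundled synthetic demo (an 8-Mbp genome, 60 genes, 12 planted
25-kbp depletion domains at factor 0.5, 20 phased arrays shifted by +15 bp,
150 TF peaks at 4× odds inside depleted domains, one 3C viewpoint):

```bash
nucleodyn run-all --outdir demo --seed 0
nucleodyn report --outdir demo
```

which prints (abridged):

```
                  metric         value
        windows_depleted     65
   scale_100000_depleted     16
nucleosomes_repositioned    863
      nucleosomes_stable   1451
                genes_up      9
          peaks_embedded     17
         peak_odds_ratio      3.018508
           peak_fisher_p      0.000359
     contact_significant    605
```

Reading: the 12 planted domains produce 65 depleted 5-kbp windows (BH
α = 0.05; ~5 windows per 25-kbp domain); at the 100-kbp scale 16 windows are
depleted (the 12 true domains plus raw-p false positives at the coarse
scale). Of ~2,300 positioned nucleosomes in expressed gene bodies, 863 moved
by >10 bp — the 20 shifted arrays — while 1,451 stayed put. 17/150 TF peaks
are embedded in depleted windows versus 65/1,600 windows depleted overall,
an odds ratio of 3.0 (Fisher p = 3.6 × 10⁻⁴), recovering the planted 4×
preference. Every stage writes plain-text outputs (TSV/BED/bedGraph) plus a
manifest with SHA-256 checksums; re-running with the same seed reproduces
every file byte-for-byte.

The same stages are available on real data via the `occupancy`, `domains`,
`reposition`, `metagene`, `embed`, `annotate`, `motif` and `contacts`
subcommands, which read BED / BED12 / narrowPeak / chrom.sizes / TSV inputs.

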