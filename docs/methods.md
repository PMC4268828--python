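# Methods

## The occupancy model

MNase digestion of cross-linked chromatin leaves ~147 bp of DNA per
nucleosome; after paired-end sequencing, a fragment's midpoint estimates the
dyad of the nucleosome that protected it. We treat the two time points of a
stimulation time course as two independent samples of midpoints from two
occupancy landscapes and ask, window by window, whether the later landscape
lost or gained occupancy beyond what stochastic sampling explains.

For a tiling of the genome into non-overlapping windows of constant size,
with per-window counts rᵢ (t₁) and sᵢ (t₂):

1. **Depth normalization.** s̃ᵢ = sᵢ·R/S rescales the t₂ counts to the t₁
   library total before anything else. This is done to the *counts*, not as
   a pseudocount-then-scale, so that uniform scaling of either library is an
   exact no-op on every downstream quantity (centred values, p-values,
   labels). The low-coverage mask (rᵢ + s̃ᵢ < 20 reads) is likewise applied
   on the normalized scale for the same reason. The cost of this choice is
   that the pseudocount's effective weight on the t₂ side tracks the t₁
   depth; at the default c = 0.5 the effect is negligible beyond the masked
   range.
2. **Log-ratio and centring.** qᵢ = log₂((rᵢ+c)/(s̃ᵢ+c)); ‖qᵢ‖ = qᵢ − Q̄,
   the mean over unmasked windows. Base 2 is a display convention — any base
   cancels in the empirical null. The sign convention puts t₁ in the
   numerator, so *positive* centred values mean *fewer* fragments at the
   later time: depletion. Browser tracks are written as −‖q‖ (later vs.
   earlier), the orientation fold-change tracks are usually drawn in.
3. **Empirical null.** Centred values from transcriptionally inert windows —
   overlapping no expressed gene, and (when RNA midpoints are supplied)
   carrying < 1 RNA read/kbp — form the null sample. We require ≥ 100 such
   windows (configurable) and reject a degenerate (constant) null. Both
   tails are kept: depletion and enrichment are tested as two one-sided
   questions against the same distribution.
4. **p-values.** p_right = (1 + #{null ≥ ‖q‖})/(1 + m) with the symmetric
   left tail; the add-one smoothing keeps p in (0, 1] and converges to the
   plain tail probability as the null grows. p is therefore floored at
   1/(m+1) — see "multiple testing" below for the consequence.
5. **Labels.** Benjamini–Hochberg per tail at α = 0.05 by default; a raw-p
   mode exists because the add-one floor makes BH unable to reject a *small*
   number of discoveries when the null has only a few hundred windows
   (BH needs p ≤ α·k/n; with m ≪ n/α no window can qualify). This is why
   the multi-scale stage (25/50/100-kbp windows, hence few null windows on
   any desk-scale genome) defaults to raw-p labelling while the 5-kbp stage
   uses BH. Both tails significant at once is impossible for α ≤ 0.5 and is
   asserted, not handled.

Assumptions: counts are (over-dispersion-free) Poisson draws from a shared
landscape; the inert regions are genuinely unaffected by the stimulus; and
library composition differences are uniform (the centring absorbs a global
shift, not locus-dependent bias). No GC/MNase-bias correction and no
replicate dispersion model is attempted.

## Dyad calling and repositioning

Midpoint counts are smoothed with a Gaussian kernel (σ = 30 bp, mass
conserved by padding the support). Dyads are local maxima accepted greedily
in height order with a 147-bp exclusion zone (one nucleosome footprint),
ties to the leftmost coordinate. Calls from two time points are matched by
mutual nearest neighbour within 73 bp (half a footprint, preventing
cross-array matches and chained assignments); a matched pair with
|Δdyad| > 10 bp is *repositioned*, unmatched calls are *lost*/*gained*.
"Differentially unmasked" regions are ±73 bp around repositioned and lost
dyads, merged.

The precision of a dyad call is set by the midpoint spread around the true
dyad (positioning fuzziness plus digestion-length jitter) over the fragment
count: at 50 fragments/nucleosome and ~16 bp midpoint SD the per-call SE is
≈ 2.3 bp, so a 15-bp shift is detected in > 90 % of nucleosomes while a 5-bp
shift exceeds the 10-bp criterion in < 10 %. At materially higher fuzziness
(≥ 20 bp SD) the 5-bp false-call rate necessarily exceeds 10 % for *any*
unbiased estimator — the criterion is a statement about both the data
quality and the threshold.

## Metagene profiles

Gene bodies are divided into ~50-bp windows and each gene's window vector is
linearly interpolated onto a fixed 100-bin axis (the target bin count is a
choice; proportional scaling itself does not fix one). Flanks of 5 kbp are
absolute 50-bp bins; minus-strand genes are reversed so the TSS is always
left; bins are summed over genes (reads-per-million rescaling is available
for cross-library display). Genes shorter than the bin count are skipped
with a warning; flank windows running off a chromosome are masked and
tracked in a per-bin coverage vector. Gene classes come from two-time-point
counts normalized by median-of-ratios size factors with fixed thresholds
(> 0.6 / < −0.6 / within ±0.01 log₂ fold-change, > 100 reads per gene at
each time point); no dispersion-aware test is applied — the classification
is the thresholds, nothing more.

## Peak association and motifs

A peak is embedded in the depleted-domain set when ≥ 25 % of *its own*
length is covered by the union of domains (a window-relative variant exists
behind a flag; with 5-kbp windows and ~300-bp peaks the two differ
materially and the peak-relative reading is the default because peaks are
the counted objects). Location classes are assigned by interval midpoint
with promoter (±1 kbp of a TSS) taking precedence over intragenic.
Fisher's exact test uses the sample odds ratio and a two-sided p summing
hypergeometric probabilities ≤ the observed one — by exact integer
arithmetic up to table total 500 (ties resolved exactly, no float
tolerance), by the vectorized hypergeometric pmf with the conventional
1 + 10⁻⁷ tie tolerance above. The IUPAC scanner reports all overlapping
match starts; reverse-strand hits scan the reverse-complemented pattern
against the forward sequence, so a palindromic consensus (GGRRNNYYCC is one)
legitimately yields one hit per strand per site.

## Contact domainogram

3C-seq signal is binarized per restriction-fragment end (an end either
witnessed a ligation junction or not), which removes read-depth effects by
construction. Enrichment is scored in sliding windows over a geometric
ladder of 12 sizes from 2 to 200 kbp, step w/10, as (positive fraction in
window)/(background rate), the background being 3,000 ends sampled uniformly
without replacement (all ends when fewer exist); windows with < 3 ends are
masked. Significance: binary labels are permuted over ends (preserving the
total), all windows rescored per permutation with the same background
indices, and the threshold is the smallest observed score t with
E[#perm ≥ t]/#obs ≥ t < 0.01. Permuting labels over ends is the natural
exchangeable null here because distance-dependence of contact probability is
already flattened by the background-ratio normalization at the scale of the
ladder; a distance-stratified permutation would be the upgrade if strong
viewpoint-proximity gradients were present.

## The synthetic generator

The generator produces the minimal structure the statistics are built to
detect, not a sequencing simulator:

- **Landscape**: a per-bp dyad-weight track, 1/NRL (NRL = 190 bp) in
  background chromatin, phased Gaussian peaks (σ = 15 bp) every NRL
  downstream of each expressed TSS. The 15-bp spread sits mid-range of
  positioned-array fuzziness and, at the stated fragment counts, is what
  makes the >10-bp repositioning criterion a sharp discriminator (see
  above).
- **Events**: multiplicative depletion/enrichment and rigid dyad shifts on
  intervals; overlapping events are rejected as contradictory. Defaults
  (factor 0.5, +15 bp) are calibration choices, not measured values.
- **Fragments**: Poisson total with mean occupancy × track mass, midpoints
  categorical on the track (hence independent Poisson counts in disjoint
  regions), lengths normal (147 ± 10 bp) clipped at 50 bp. Midpoints, not
  5′ ends, carry the signal.
- **Annotations**: non-overlapping genes with exact planted log₂
  fold-changes per class (no count noise — the classifier's thresholds,
  ±0.01 for constitutive genes, are far inside Poisson noise at realistic
  depth, so noisy counts would test the noise, not the classifier);
  TF peaks placed inside depleted intervals with probability
  odds·f/(odds·f + 1 − f); inert regions are the genome minus expressed
  genes *and minus planted events* (± 2 NRL), because a region with planted
  activity is by construction not a sample of pure stochastic fluctuation.
- **Contacts**: ApoI-like fragment ends every ~500 bp, Bernoulli-positive at
  a background rate (0.05) or a signal rate (0.9) inside planted targets.

What the generator does *not* emulate — sequence composition, GC/MNase bias,
replicate variance beyond Poisson, distance decay of 3C contacts,
inter-chromosomal contacts — bounds what passing tests mean: they establish
the correctness and calibration of the statistics under the stated sampling
model, not robustness to real-data biases.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 5–12 Mbp genomes,
20–30 fragments/nucleosome for domain recovery (≈ 1.6 M fragments per time
point at 10 Mbp), 50 for repositioning, 2-Mbp viewpoints with ~4,000
fragment ends and 100 permutations. These sizes were chosen so each
guarantee is measured on ≥ 2,000 windows / ≥ 2,000 nucleosomes / ≥ 10⁵
domainogram windows while a full run stays in minutes on one CPU; all
statistics scale linearly in fragments and windows.

Tie-breaks and degenerate inputs are fixed policies, not incidental:
left-most wins for equal-height dyads and equidistant matches; empty
midpoint sets give empty densities; an all-identical null, an all-masked
grid, an all-positive contact profile and a zero-margin Fisher table are
errors (or, for the contact profile, an empty result with a warning) rather
than silently degenerate numbers. Seeds flow from a single integer root through
`numpy.random.SeedSequence.spawn`, one generator per stage, never global
state.

## Known limitations

- The empirical null is genome-wide (chromosome-pooled) by default; strong
  per-chromosome composition differences would call for the per-chromosome
  flag.
- BH on an empirical null cannot reject below 1/(m+1); coarse scales use
  raw-p labelling and should be read as display-level calling.
- The dyad caller is a transparent stand-in for dedicated peak callers; it
  makes no attempt to deconvolve overlapping fuzzy nucleosomes closer than
  147 bp.
- The domainogram permutes labels globally; it does not model
  distance-dependent contact decay.
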