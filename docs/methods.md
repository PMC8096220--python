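# Methods

`polpause` detects RNA polymerase II pausing sites from strand-specific,
single-nucleotide nascent-transcription occupancy (NET-seq-style 3'-end
counts), removes the library-preparation artifacts that mimic pauses,
classifies the surviving sites genomically, derives DNA/RNA sequence
features around them, and models pause determinants with a random forest.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic fixtures do and do not establish.

## The pause-detecting statistic

A candidate pause is a strict local maximum of the occupancy signal:
position *i* with `x[i-1] < x[i] > x[i+1]` (absent neighbours count 0).
Plateaus of tied counts are never candidates; the strict definition is
taken literally, and adjacent co-maximal positions are therefore excluded
by construction.

Each candidate is evaluated against the null hypothesis that polymerase
does not accumulate anywhere locally: the M reads found in the window of
length L = 200 nt centred on *i* are redistributed uniformly over the l
occupied positions of that window, and the maximum per-position count of
each redistribution forms the null pool (N = 10 000 by default). The
p-value uses the add-one permutation form

    p = (1 + #{null max >= observed}) / (N + 1),

which is valid by construction and never returns 0 on discrete ties; a
`strict` flag reproduces the literal fraction `#{null max > observed}/N`
for comparison. Benjamini–Hochberg correction is applied across **all**
local maxima of a sample (all contigs, both strands pooled — the simplest,
most conservative family); q < 0.05 is called significant.

### Exact null tail

The resampling null — the maximum cell count of a uniform
multinomial(M, l) — has an exact tail, computed by Poisson conditioning:
with X₁..X_l iid Poisson(M/l), the cell counts are distributed as
(X | ΣX = M), so P(max ≤ c, ΣX = M) is the M-th coefficient of the l-fold
convolution of the truncated Poisson pmf (self-convolution by squaring,
truncated at M+1 terms), normalised by Poisson(M).pmf(M). The exact tail
replaces resampling whenever the convolution work `(M+1)² · log₂(l)` is
below `exact_cutoff` (default 10⁶) — on sparse tracks this covers nearly
every candidate, making calls deterministic and fast; the per-site
`method` column records which route was used. Null pools for the
resampling route are cached per (M, l) and seeded per (M, l) from the run
seed, so results are bit-reproducible and independent of candidate order.
Window edges are clipped at contig boundaries.

## Artifact model

Two artifacts create spurious single-base spikes:

* **PCR duplicates** — collapsed on (contig, strand, 3'-end, UMI).
  An optional `hamming1` mode additionally merges UMIs at Hamming
  distance ≤ 1 into a higher-count UMI at the same position (greedy by
  descending count, lexicographic ties), covering the dominant
  sequencing-error mode at 10-nt UMI length.
* **RT mispriming** — the RT primer anneals to adapter-like sequence
  inside the nascent RNA, so the read's "UMI" is actually the genomic
  10-mer immediately downstream (in transcription direction) of the
  apparent 3' end. Downstream is interpreted strand-aware: `[end3+1,
  end3+11)` on +, reverse-complemented `[end3-10, end3)` on −, i.e. the
  bases a correctly primed RT would have copied next.

The filter removes reads whose UMI equals that downstream 10-mer exactly;
positions where the exact-match fraction (computed on pre-removal
denominators) is **strictly** greater than 5% are prone positions and
masked entirely. Escape quantification follows the estimator's published
logic: among reads at prone positions, any UMI with positionwise identity
≥ 50% to the downstream 10-mer (N never matches) counts as a mispriming
event, and the escaped fraction is the share of events without an exact
match. Deduplication precedes filtering in the pipeline; note that
exact-match mispriming reads at one locus share their "UMI" and collapse
under deduplication, which biases the escape estimate upward — the escape
quantification in the acceptance checks is therefore run on the
pre-collapse read set (no PCR duplication is simulated there, so nothing
else is conflated). Reads whose 3' end lies within 10 nt of a contig edge
cannot be tested and are kept.

Splicing and 3'-cleavage intermediates are handled by masking, per gene
strand, the 3'-most base of every annotated exon and intron plus every pA
site (genomic `end−1` on +, `start` on −), before counting 3' ends.

## Genomic classification

Categories, in precedence order, for a site at position *p*:

1. **promoter-proximal** — same strand, within `[TSS, TSS+300]`
   (inclusive) downstream of *any* annotated TSS of a gene. Promoter
   windows of downstream alternative TSSs take precedence over gene-body.
2. **undetermined** — *p* falls simultaneously in the gene-body region of
   one gene and the antisense region of another.
3. **gene-body** — same strand, in `(TSS+300, pA]` from the most upstream
   TSS to the 3'-most pA; subclass `exonic` iff overlapping an annotated
   exon, else `intronic`.
4. **antisense** — opposite strand, within `[most-upstream TSS − 1000,
   most-downstream pA]`; subclass `divergent` upstream of the TSS,
   `convergent` over the body, `undetermined` when several genes imply
   conflicting subclasses.
5. **intergenic** — everything else; subclass `termination-zone` within
   3.5 kb downstream of a pA, else `enhancer` inside a supplied enhancer
   interval, else `other-intergenic`.

Splice proximity uses the half-open exon-boundary coordinate as the
junction position and a strict 40-nt radius; a site near several junctions
receives every matching label, with first/last exon ordering taken in
transcription direction. Matched non-pausing controls are drawn uniformly
from `[p+x, p+x+20]` or `[p−x−20, p−x]` (side uniform; x = 50 for
promoter-proximal, 300 otherwise), rejecting draws on pause or masked
positions (≤ 50 attempts, then the pause is dropped from the paired set).
Active genes are TPM strictly > 1. The premature-termination rule flags
sites whose 3'-end-signal density strictly exceeds the 25th percentile
(linear interpolation) of the density at pA sites.

## Sequence features

Relative coordinates anchor the pause base at **−1** (the last nucleotide
added to the nascent RNA); **+1** is the NTP-insertion site; there is no
position 0; the RNA–DNA hybrid spans −10..−1. All sequence is reported on
the coding strand, 5'→3' in transcription direction (minus-strand sites
are reverse-complemented), which also fixes the convention for the
nucleotide-identity features. The species-universal feature block (35
columns):

* **Skew differences (6)** — XY skew `(|X|−|Y|)/(|X|+|Y|)` of the 20-nt
  window downstream minus the 20-nt window upstream, with near edges 10 nt
  from the site (`[+10,+29]` and `[−29,−10]`); skew is 0 for an absent
  pair. The alternative reading of the window placement (`[−20,−1]` /
  `[+1,+20]`) was considered and rejected in favour of windows clear of
  the hybrid region.
* **Nucleotide identity (24)** — one-hot bases at +1, −1, −2, −3, −10,
  −11 (active centre and both hybrid ends). An N in any required window
  drops the site rather than imputing.
* **Hybrid thermodynamics (4)** — ΔH, ΔS, ΔG37 and Tm of the 10-bp
  RNA/DNA hybrid from nearest-neighbour parameters (Sugimoto et al. 1995
  RNA/DNA set, shipped as a swappable TSV): initiation plus nine steps;
  ΔG37 = ΔH − 310.15·ΔS/1000; Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) with
  R = 1.987 cal/(mol·K) and C_T = 10⁻⁴ M, no salt correction. Absolute
  calibration is irrelevant to the classifier (any monotone transform
  preserves tree splits).
* **Nascent-RNA MFE (1)** — minimum free energy of the stretch −29..−11
  (the hairpin-formation region just outside the polymerase), from a
  builtin Nussinov-style dynamic program over a pure stacking model:
  Watson–Crick and GU pairs, stack energy −(w₁+w₂) with w(GC) = 1.5,
  w(AU) = 0.9, w(GU) = 0.5 kcal/mol, isolated pairs free, minimum hairpin
  loop 3. Deliberately simple and documented; exact for its own energy
  model (verified against exhaustive structure enumeration), and intended
  as a monotone structure-propensity score rather than Turner-grade
  energetics. The engine name is recorded in the matrix provenance.

Optional resource-backed blocks: pentamer **DNA-shape** statistics (min,
max, mean, span, mean |successive difference| of MGW/Roll/ProT/HelT/EP
over the 16 pentamer centres covering 10 nt upstream to 5 nt downstream);
**PWM presence flags** for TF motifs in three regions (polymerase
footprint ±25 nt, plus 100-nt flanks beyond it; both strands) and RBP
motifs (upstream region only, given strand — its complement is the
nascent RNA); mean **methylation** over covered CpGs within ±100 nt (0
plus a coverage flag when uncovered); and **interval-overlap flags**
(non-B DNA, G4 predictions, …) within ±100 nt.

PWM hit thresholds are exact: the null score distribution of a random
background sequence is the convolution of the per-column 4-point score
distributions (scores merged on a 10⁻⁹ grid), and the threshold is the
smallest score whose tail mass is ≤ the requested per-window p (10⁻⁴
default) — conservative on discrete score levels by construction. A 10⁻⁶
guard absorbs grid rounding during scanning.

Enrichment logos are per-position log₂((f+ε)/(b+ε)) with ε = 0.01 between
foreground and background base frequencies, columns labelled by relative
position.

## The classifier

A balanced matrix of pause and matched non-pause sites is split
stratified: ~20% tunes the forest's hyperparameters (grid over number of
trees {100, 300, 500}, depth {∞, 10, 20}, min split {2, 10}, min leaf
{1, 5}; internal 3-fold CV scored by PR-AUC; ties broken toward the
smaller model), and the remaining 80% is scored by stratified 10-fold
cross-validation (5-fold supported), PR-AUC per fold. Tune rows are never
reused for evaluation.

Permutation importance is computed on held-out folds: per fold, each
feature column is shuffled `importance_repeats` times and the importance
is the baseline PR-AUC minus the permuted PR-AUC. Repeats within a fold
share one fitted model and one held-out set, so they are **averaged
within fold** before testing; a one-sided one-sample t-test (mean > 0)
across the k per-fold means, BH-corrected across features, marks
significance at q < 0.05 with a positive mean. Testing the raw
repeats×folds pool instead was evaluated and rejected: it pseudo-
replicates correlated drops and flags noise features whose tiny positive
importance merely reflects forest overfitting.

## Synthetic data: what it emulates, and what it does not

The generators produce i.i.d.-base genomes at a set GC content; genes
laid along the contig with multi-exon structure, alternating strands,
optional antisense-overlap loci, and intergenic enhancers; occupancy as
uniform background reads within transcribed spans (exactly the caller's
null, so the calibration test is a true type-I-error measurement) plus
planted single-nucleotide pauses; reads with random decamer UMIs,
configurable PCR duplication, and mispriming planted at arbitrary genomic
loci (the filter keys on UMI/genome identity, not adapter content) with
per-base UMI corruption producing escaped events at the closed-form rate
1 − (1 − ε)¹⁰.

A planted pause's count is `pause_fold` × the mean count of occupied
positions in the surrounding 200-nt window (at least 2) — the fold is an
amplification over the *occupied-position* mean, since a multiple of the
sparse per-nucleotide rate would plant sub-significant 2-read spikes.
Planted positions keep ≥ 10 nt spacing so each remains a strict local
maximum. Default study conditions: 1-Mb genome, 50 genes, 0.1 reads/nt
background, 20-fold pauses at 0.5/kb of transcribed sequence (~200
genome-wide).

Not emulated: realistic sequence composition and isoform structure,
base-call errors inside reads, splicing-intermediate 3' ends beyond the
masking rule, overdispersed or gene-length-dependent coverage. Passing
tests therefore establish the algorithmic properties (calibration,
recovery, artifact removal, feature arithmetic, model behaviour) under
the stated statistical model — not performance on any particular real
data set.

## Problem sizes and numerical notes

The test suite and the acceptance script use the sizes above (1-Mb
recovery fixture; 20 × ~130k-read null tracks; ≥ 10⁴ planted mispriming
events; n = 2000 × 40-feature model matrices, 10 seeds in the suite and
1 in the script; 10⁵-draw resampling checks against the exact tail).
Quantile computations use linear interpolation; the Welch intensity
comparison is one-sided (gene-body > promoter-proximal), matching the
direction the statistic is meant to detect; Fisher tests are two-sided.
Every stochastic entry point takes an explicit seed, and all outputs are
bit-reproducible given one.

## Known limitations

* Plateaus (tied adjacent maxima) are never called; a genuine pause
  spread over two bases at identical counts is invisible to the strict
  local-maximum rule.
* The BH family pools both strands of a whole sample; per-region
  correction is not implemented.
* The builtin MFE model ignores loop entropies and dangling ends; an
  external folding engine can be substituted where absolute energies
  matter.
* UMI collapse (`exact`/`hamming1`) replaces full message-passing UMI
  clustering; at 10-nt UMIs and NET-seq depths the dominant error mode is
  covered, but heavily saturated positions may under-collapse.
* Which annotation intervals to mask (abundant RNA classes etc.) is left
  to a user-supplied BED; no attempt is made to reproduce any particular
  release's mask.
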