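# Methods

This note documents the models behind `cffrag`: what is computed, which
parameters matter, what the synthetic generator does and does not emulate,
and the numerical choices a maintainer would want written down.

## Fragment model and coordinates

A cfDNA fragment is a genomic interval in 0-based half-open coordinates;
its length is `end − start`.  From paired-end alignments one fragment is
emitted per properly paired, primary, non-duplicate pair, from the leftmost
mate, spanning `start .. start + |TLEN|`; pairs with TLEN = 0 are dropped
and both mates must reach the MAPQ cutoff (default 30, conventional for
low-pass WGS).  Long-read fragments use the reference span of the primary
alignment, which is robust to soft-clipped ends.  Lengths above 10,000 bp
are kept in an overflow bucket that still counts in every denominator.

## Size features

All size features derive from the exact integer length histogram.
Range proportions use inclusive endpoints; the canonical windows are
100–155 bp (short), 250–10,000 bp (long), 50–700 bp (the electrophoresis
comparison window), plus 50–150 bp as the window used when correlating
shortness with tumor fraction — both short windows exist because both are
used in practice, and silently picking one would change results.  The modal
size is the argmax over 100–200 bp with ties to the smaller length.  The
periodicity score makes the qualitative "10 bp periodicity" claim testable:
the log of the in-band (80–150 bp) counts is linearly detrended and the
spectral power at 1/(10 bp) is divided by the median power at frequencies
within a factor of two of it (excluding a ±0.015 cycles/bp guard band).  A
flat or unstructured density scores ≤ ~1; sampled ladders with the comb on
score in the tens.

## End motifs

Both physical ends of a double-stranded fragment are 5′ termini, one per
strand, so the left end window `[start−k, start+k)` is read forward and the
right end window `[end−k, end+k)` as its reverse complement; position +0 is
the first fragment base and negative positions lie upstream (outside).
Windows containing N or running off the contig are skipped and counted.
The default k = 5 keeps the full heat-map window while the biology of
interest (upstream T enrichment, terminal C preference in humans) sits at
−2..+1.  Bias is observed minus background frequency, where the background
is the composition of uniformly sampled genomic windows counted in both
orientations — the simplest defensible null, and the deterministic
two-orientation counting avoids strand-sampling noise that would otherwise
contaminate an all-deterministic comparison.  Cohort-level matrices take the
per-sample median per cell before differencing groups (pooled-end mode is a
flag), making the group difference antisymmetric by construction.  Note one
consequence of the strand convention: on a homopolymer reference the end
matrix is an exact A/T split, not pure A.

## qPCR quantification

Standard curves are ordinary least squares of Cq on log10(ng) over replicate
means; efficiency is `10^(−1/slope) − 1` and a non-negative slope marks the
curve invalid.  Quantification inverts the curve after averaging replicate
Cqs on the Cq scale.  The short index `(LINE − PECAM)/LINE` is the fraction
of cfDNA amplifiable only by the short amplicon; a negative value (long
assay above short) is reported with a flag rather than clamped so downstream
statistics see the raw measurement.  Pre-quantified digital-PCR pairs can be
fed to the same index.

## Tumor fraction

Fragment midpoints are counted in 500 kb bins; bins with zero count or GC
outside [0.30, 0.60] are masked (standing in for a mappability track).
Depth is divided by a lowess fit of count on GC normalized to mean one, with
the total unmasked count preserved; constant GC degenerates to the identity.
Log2 ratios are taken against the sample median (or a supplied
panel-of-normals reference).  The estimator then runs a Gaussian-emission
HMM over copy states {1,2,3,4} with state means
`μ_c(tf) = log2((tf·c + (1−tf)·2)/2)`, a shared emission sd of
`max(1.4826·MAD, 0.01)`, uniform initial probabilities and self-transition
1 − 1e−4, evaluating the forward log-likelihood on a tf grid 0..0.90 step
0.01; the returned tf is the grid argmax (ties to the smaller value, so a
copy-neutral sample returns 0), Viterbi at that tf gives per-bin copy calls,
and tf > 0.03 defines detection.  This deliberately replaces a full
ichorCNA-style EM over ploidy and subclonality: the diploid anchor c = 2
with no ploidy re-centering avoids the tf–ploidy identifiability trap on
synthetic data, at the cost of not modeling whole-genome doubling —
a documented limitation, not a target of numerical agreement with any
published tumor-fraction table.

## Classification

Four features per sample — qPCR short index, HMM tumor fraction, WGS short-
and long-fragment proportions — feed a 500-tree random forest
(√p features per split, unlimited depth, no class weighting; the framework
is fixed so results are attributable to the features, not tuning).
Cross-validation is grouped by subject: each fold holds out every sample of
one dog, trains on all rows of the others, and records out-of-fold scores;
pooled scores form one ROC.  Two modes mirror longitudinal designs:
`all_samples` scores pre- and posttreatment rows of the held-out dog;
`pretreatment_only` restricts both training and testing to one pretreatment
row per dog (healthy dogs, which have no treatment axis, stay eligible).
AUC uses the midrank formulation, identical to Mann–Whitney U/(n₁n₂);
operating points maximize sensitivity subject to specificity ≥ target with
strict `score > threshold` predictions and ties broken toward the more
specific cut.  Per-fold forest seeds derive from the master seed and the
subject id by CRC32, so results are reproducible and independent of fold
order.

## Statistics

Two-sided p-values throughout.  Mann–Whitney uses midranks, exact
enumeration when n₁+n₂ ≤ 12 without ties and the tie- and
continuity-corrected normal approximation otherwise; IQR is Q3 − Q1 with
linear-interpolation quantiles.  Fisher's exact reports the sample
(cross-product) odds ratio with the standard two-sided hypergeometric
p-value.  No multiple-testing correction is applied anywhere.

## The synthetic cohort generator

The generator defines the study conditions under which everything above is
validated.  A fragment-length distribution is a four-component mixture:
a sub-mononucleosomal tail (exponential approach to the mono peak over
50..mono−sd bp, modulated by `1 + a·cos(2πℓ/10)` with default amplitude
0.45), Gaussian mono- and dinucleosome peaks, and a geometric
polynucleosomal ladder with unit spacing `di − mono`.  The species presets
encode the observed contrasts: human mono 166 ± 8 bp with a dominant
mononucleosome (weights 0.08/0.72/0.14/0.06); healthy canine mono 153 ± 9 bp,
dinucleosome at 440 bp (~100 bp above human), and a heavy long-fragment
compartment (weights 0.10/0.40/0.16/0.34, ladder decay 0.85 up to 30 units)
— this tail is what depresses the canine short index (~0.30 expected) and
electrophoresis fraction relative to humans; tumor canine mono 144 ± 10 bp
with an enriched sub-mononucleosomal tail and depleted long fragments
(0.30/0.58/0.06/0.06).  The sub-mono support ends one mono-sd below the peak
so the modal length equals the configured mono mean exactly.

A cancer sample at tumor fraction tf draws each fragment from the tumor
ladder with bin-local probability `tf·c/(tf·c + (1−tf)·2)` and expected bin
depth proportional to `(1−tf)·2 + tf·c`, with c from the subject's CNA
segments (default: one loss c=1 and one gain c=3 covering 20% of the
genome).  End bias is planted by rejection sampling (≤ 50 attempts) of
fragment positions against a 5-position weight matrix at both 5′ ends,
which keeps a single consistent reference for end-motif analysis.
Reference genomes have per-500kb-bin GC following a smooth sinusoid over
0.35–0.55 with a ~4 Mb period — short enough that GC stays decorrelated
from multi-bin CNA segments, which matters because a GC profile collinear
with a segment lets the lowess correction absorb the copy-number signal.

Per-subject biological variability is one latent "long-fragment burden"
factor (sd 0.5) that jitters the ladder decay on the logit scale and the
di+poly weight on the log scale together; this reproduces the large healthy
inter-individual spread of the short index (IQR ≈ 0.1) seen in real dogs.
Cohort qPCR is simulated from the subject's plasma-level length
distribution (the assay interrogates orders of magnitude more molecules
than are sequenced), with Normal Cq noise of sd 0.05 per replicate — a
typical replicate SD for a strong TaqMan target — and the noise-free short
index recorded as truth.

For classifier studies a second, feature-level generator draws the four
features directly from lognormal distributions matched to the cohort
medians and IQRs of real canine plasma (healthy qPCR short index
0.196/IQR 0.095 vs cancer 0.47/0.33; WGS short proportion 0.31/0.07 vs
0.42/0.17; long proportion medians 0.194 vs 0.121 with log-sd 0.30 where the
spread is unreported; tumor fraction detected in ~55% of cancer samples with
detected median 0.184).  Lognormals were chosen for positivity and right
skew; the implied single-feature separations (short-index AUC ≈ 0.91, long
proportion ≈ 0.87) follow from those printed numbers rather than from any
fitting.  A subject-level latent factor shared across features (and across
a subject's repeat samples) induces realistic cross-feature correlation
while preserving the marginals.

### What the generator does not emulate

Sequencing error, read-level artifacts, GC amplification bias beyond the
depth model, absolute plasma DNA concentrations, mappability structure, sex
chromosomes, and subclonal copy-number states.  Passing tests on this
generator therefore show that the estimators recover what they are designed
to measure under clean nucleosomal-ladder assumptions — they do not certify
performance on real libraries, where alignment artifacts and biological
heterogeneity add variance the generator does not model.

## Problem sizes and determinism

Validation runs use desk-scale problems chosen to keep every check
statistically meaningful: tumor-fraction recovery uses a 100 Mb genome
(200 bins) at 500 fragments per bin across 10 seeds; end-bias recovery uses
~8k fragments per seed; classifier checks use 20+20-subject cohorts across
10 seeds.  Every random draw flows through seeded `numpy.random.Generator`
instances; the pipeline fans a master seed out to stages by hashing stage
names, so stage results are stable under pipeline reordering and identical
configurations reproduce outputs byte for byte.

## Known limitations

The tumor-fraction estimator shares ichorCNA's inference principle but not
its ploidy/subclonality machinery; its estimates are not comparable to
published tumor-fraction tables.  The qPCR model treats amplifiable
template as `(ℓ − L + 1)⁺` per fragment — random amplicon position within
the fragment — ignoring polymerase length bias.  The short index responds
only weakly to tumor admixture at low tumor fraction when the background is
long-fragment-rich, so cohort-level index contrasts are smaller than those
observed in real dogs, where disease also shifts the non-tumor cfDNA
compartment; the feature-level generator sidesteps this for classifier
studies by calibrating to observed cohort statistics directly.
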