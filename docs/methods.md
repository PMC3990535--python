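# Methods

## Signal model and synthetic data

The generator emulates a two-channel tiling aCGH experiment. A layout
places `floor(L/spacing)` probes per chromosome at multiples of the
spacing (default 2509 bp, the genome-wide median of the emulated 720K
platform) and scatters them over the scanner grid by a seeded random
permutation, so spatial artifacts are statistically independent of
genomic position — the assumption spatial correction relies on.

Copy-number truth is a set of non-overlapping regions, each carrying an
expected mean log2-ratio offset: +0.4 (gain), −0.4 (loss), +1.3
(amplification), −1.3 (deletion) by default. The magnitudes are
arbitrary apart from comfortably clearing the 0.25 and 1.0 calling
thresholds, and are configurable; copy number is never represented as
integer copies because the calling rules operate purely on mean log2
ratios. Channel intensities are generated as

    ref_i  = B · 2^(−e_i/2)
    test_i = B · 2^(shift_i + gx·X_i + gy·Y_i + bias + e_i/2),

with `e_i ~ N(0, σ)`, so both channels are positive by construction and
the log2 ratio is exactly `shift + gradient + bias + e`. Defaults:
baseline B = 1000 a.u., noise σ = 0.15 (chosen for testability — the
noise level of the degraded-archival-tissue arrays this emulates is not
known), gradient and dye bias 0 unless set.

Cohorts draw each recurrent region independently per sample as
Bernoulli(penetrance) and add a Poisson number (default mean 2 per
sample) of private CNVs of 25–75 probes, placed uniformly without
overlap. qPCR tables set group ΔCt means to −log2(expression) so that
the realized group fold equals the requested fold exactly at zero
replicate noise; the default replicate noise is 0.3 cycles applied
independently to target and reference wells, and group sizes default to
the 26-vs-14 validation design.

What the generator does **not** model: GC waves, probe sequence
effects, saturation, background, FFPE degradation, mosaicism. Passing
tests therefore demonstrate correctness of the analysis chain under an
additive-Gaussian ratio model with exchangeable spatial placement, not
robustness to every artifact of real archival arrays.

## Preprocessing

`log2_ratio` is the probe-wise log2(test/ref). Spatial correction fits
a locally weighted polynomial (LOESS) surface over the grid coordinates
— for each probe, the nearest `span·n` neighbours (default span 0.3)
enter a degree-2 weighted polynomial fit under tricube weights — and
subtracts it, adding back the fitted surface's mean so the correction
is exactly mean-preserving. Correction operates on log2 ratios rather
than per channel; for ratio-level bias the two are equivalent and the
ratio form is simpler to verify. A small ridge jitter (1e−10) keeps
collinear neighbourhoods solvable, and the fit is evaluated in chunks
to bound memory.

q-spline normalization maps the quantiles of the test channel onto the
reference channel's: anchors at quantiles k/(n_anchors+1)
(n_anchors = 14) of the log2 intensities define a monotone cubic
(PCHIP) map, extended with **unit slope** (constant offset) beyond the
outermost anchors. The unit-slope tail was a deliberate choice: a
secant-slope continuation multiplies quantile-estimation noise over the
long intensity tails, exactly where genuine amplification and deletion
signal lives, and measurably biased recovered amplification means;
constant offset treats the tail as a pure shift, stays monotone (rank
order is preserved globally) and absorbs global channel scaling
exactly. Degenerate (non-increasing) anchors trigger a warned fallback
to piecewise-linear quantile mapping.

Stage order is configurable. The default `spatial-first` (correct on
raw ratios, fold the corrected ratios back into an adjusted test
channel, then quantile-map) matches the platform's documented order and
behaves better: normalizing first lets an uncorrected gradient widen
the test-channel distribution, and the quantile map then shrinks true
CNV shifts. Both orders satisfy the same invariants (mean behavior,
rank preservation, shift equivariance) and both are exercised in the
tests.

Quantile normalization assumes the two channels share a distribution up
to artifacts, so it attenuates CNV signal in proportion to the genome
fraction altered. The bundled demo genome (8 chromosomes × 600 probes)
keeps the implanted footprint at a few percent, matching the
genome-wide-array regime; on small custom layouts where CNVs cover tens
of percent of all probes, normalization visibly compresses the signal —
that is a property of the method, not a bug.

## Segmentation

For a chromosome's series x₁…xₙ, `best_partition_sse` returns the exact
k-segment partition minimizing total within-segment squared error,
via a suffix dynamic program over prefix sums (O(k·n²), no incremental
variance updates). Ties are resolved to the lexicographically smallest
breakpoint vector by reconstructing greedily from the left and taking
the earliest split that achieves the optimum, making results
deterministic across platforms.

Model selection: k\* = argmin_k [SSE(k) + λ·k], k ≤ kmax (default 25).
The default penalty is λ = 3·σ̂²·log n with σ̂ = MAD(Δx)/(√2·0.6745),
the median-absolute-deviation estimate of probe noise from first
differences (differencing removes piecewise-constant signal; the MAD
resists breakpoint outliers). A classic BIC accounting — two free
parameters per extra segment — would give the coefficient 2, but
breakpoint positions are chosen by a scan over all split points, which
inflates the largest spurious SSE gain on pure noise above its nominal
χ² size; with the coefficient 2 a pure-noise chromosome of 500 probes
is split in roughly 6% of realizations, with 3 in under 1%, while any
segment that survives the retention filter (≥ 5 probes, |mean| ≥ 0.25)
clears the heavier penalty several-fold at the default noise level.
Score differences below a float tolerance of 1e−8·(SSE(1)+1) are
treated as ties (prefix sums carry O(n·eps) rounding, and an exact-zero
noise series would otherwise chase 1e−13 artifacts into spurious
segments); ties go to the smallest k.

Segmentation is strictly per-chromosome; missing probe values are
dropped with a warning before the DP.

## Calling, recurrence, annotation

Calls are segments with ≥ 5 consecutive probes and |mean log2| ≥ 0.25,
classified with inclusive thresholds (≥ 1.0 amplification, ≥ 0.25
gain, ≤ −0.25 loss, ≤ −1.0 deletion). The retention bound and the
gain/loss classification boundary default to the same 0.25 but are
independent knobs, so loosening retention never relabels sub-threshold
segments.

Recurrence builds minimal common regions: per chromosome, every call
start and every call end+1 is an atomic boundary; each atomic interval
in the covered footprint counts the distinct samples per class covering
it, with nesting (amplification ⇒ gain, deletion ⇒ loss, as the
combined gain+amplification reporting of such cohorts requires), each
sample contributing at most once per region and class; adjacent atoms
with identical count vectors merge. Both recurrence thresholds are
compared inclusively (≥ 50% for gain/loss, ≥ 20% for
amplification/deletion) because published tables of this design list
rows at exactly the threshold.

Annotation uses 1-based inclusive coordinates internally (the
convention of printed region tables); BED's 0-based half-open form is
converted only at file boundaries, and "chr12"/"12" naming dialects are
normalized. A feature maps to a region iff their closed intervals share
≥ 1 bp (no minimum-overlap fraction; strand ignored). Circos track
files are written one per class with the standard color legend
(gain orange, loss purple, amplification red, deletion green); plot
rendering itself is out of scope.

## Enrichment

The over-representation statistic is the exact hypergeometric upper
tail P(X ≥ k) for k of n query features falling in a K-member term
within an N-member universe, evaluated in log space from a cached
log-factorial table with logsumexp (verified against exact rational
arithmetic to < 1e−10 relative error for all N ≤ 60). The universe
defaults to all features of the supplied annotation. An EASE-style
conservative variant (one overlap member removed) is available behind a
flag; Benjamini–Hochberg adjusted p-values are always attached, while
the default significance rule is raw p < 0.05. Terms group by
single-linkage clustering (connected components) on Cohen's kappa of
their membership vectors at threshold 0.5; each cluster's
representative is its lowest-p term (ties lexicographic), clusters
whose best p ≥ 0.05 are dropped, and the cluster score is the negative
mean log10 p of members. Kappa is defined as 1.0 for identical constant
vectors, where chance agreement is total.

## qPCR validation

Triplicate Ct values are averaged per well set (missing replicates
dropped with a warning), ΔCt = Ct(target) − Ct(reference), expression
2^−ΔCt, fold change = mean(tumor)/mean(control). The group test is an
independent-samples t-test on the expression values (matching the
validation design) with Welch's correction by default — the
pooled-variance variant and a ΔCt-scale test sit behind flags, since
expression-scale values are right-skewed and heteroscedastic and the
original variance assumption is unstated. Replicate outliers are
flagged, never removed.

## Recovery study and problem sizes

`cnvseg.evaluation.cohort_recovery_study` is the controlled end-to-end
benchmark: 20 samples on the 8×600-probe demo layout, one recurrent
gain (100 probes, +0.4, penetrance 0.6) and one recurrent amplification
(70 probes, +1.3, penetrance 0.35), noise σ = 0.15, private CNVs off so
recovered frequencies are comparable with realized carriage exactly.
Measured outcomes: both regions reappear in their frequency tables at
exactly the realized carriage whenever it clears the table threshold,
and detected breakpoints fall within ±2 probes of truth in ≥ 90% of
carrying samples (typically 95–100%). The demo genome size, kmax = 25
and the 2000-probe single-array spatial benchmark were chosen as the
smallest sizes at which the asymptotic behavior of each component is
visible; all are parameters, not constants.

## Known limitations

* The segMNT-style model-selection rule (penalty form, noise estimator)
  is this package's own reproducible choice; the original tool's
  criterion is unpublished.
* Quantile normalization attenuates signal when the altered genome
  fraction is large (see above).
* Enrichment p-values are not those of the DAVID/TAM web services —
  their exact statistics and backgrounds are proprietary or unstated;
  this package computes the exact hypergeometric tail instead.
* Recurrence frequencies are computed over minimal common regions, not
  over any externally defined region list; whether the original
  analysis merged regions before or after frequency computation is
  unstated.
* No genome-build liftover, no integer copy-number estimation, no
  mosaicism or tumor-purity modeling, no GISTIC-style significance of
  recurrence.
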