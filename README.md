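# cnvseg — array-CGH copy-number analysis

`cnvseg` re-implements, as a tested and reusable pipeline, the analysis
chain used to profile DNA copy-number variation in tumor cohorts with
two-channel array comparative genomic hybridization (aCGH): per-probe
log2 ratios from the test and reference fluorescence channels, spatial
(X, Y grid) artifact correction by locally weighted polynomial
regression, q-spline between-channel normalization, exact least-squares
segmentation by dynamic programming, threshold-based CNV calling,
cohort-level recurrence over minimal common regions, gene/miRNA
annotation with Circos track output, hypergeometric term enrichment
with kappa annotation clustering, and ΔCt qPCR validation.

Because public aCGH data for this design are not bundled, the package
ships a first-class synthetic-data generator that emulates a
NimbleGen-style tiling layout (one probe per 2509 bp) with implanted
CNVs, spatial gradients, dye bias, per-probe noise, cohort-level
recurrent regions with configurable penetrance, and triplicate qPCR Ct
tables — all with known ground truth, so every downstream stage is
testable end to end.

## The model in brief

For probe *i* with test intensity *T<sub>i</sub>* and reference
intensity *R<sub>i</sub>*, the signal is *x<sub>i</sub>* = log2(*T<sub>i</sub>*/*R<sub>i</sub>*);
0 is copy-neutral. Each chromosome's ordered series is partitioned into
*k* segments minimizing the within-segment squared error

&nbsp;&nbsp;SSE(k) = Σ<sub>segments</sub> Σ<sub>i∈seg</sub> (x<sub>i</sub> − x̄<sub>seg</sub>)²,

solved exactly in O(k·n²) by dynamic programming over prefix sums; *k*
is chosen by k\* = argmin<sub>k</sub> [SSE(k) + λk] with a robust
noise-scaled penalty λ = 3σ̂² log n. Segments with ≥ 5 probes and
|mean log2| ≥ 0.25 are retained and classified: mean ≥ 1.0
amplification, ≥ 0.25 gain, ≤ −0.25 loss, ≤ −1.0 deletion (all
boundaries inclusive). Across a cohort, call breakpoints partition the
genome into minimal common regions; regions altered in ≥ 50% of samples
(gain/loss) or ≥ 20% (amplification/deletion) make the recurrence
tables, with amplification counting toward gain and deletion toward
loss. Enrichment of term sets among region-mapped features uses the
exact hypergeometric upper tail P(X ≥ k), and qPCR validation uses
ΔCt = Ct(target) − Ct(reference), expression 2^−ΔCt, group fold change
and Welch's t-test.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
data (intermediates in `scratch/`, tables in `results/`):

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_preprocess.py
python analysis/03_segment_and_call.py
python analysis/04_recurrence.py
python analysis/05_annotate_and_enrich.py
python analysis/06_qpcr_validation.py
```

With seed 1 the simulation prints

```
simulated 20 samples x 4800 probes (8 chromosomes) -> scratch/sim
  recurrent gain chr1:629759-878150 (penetrance 0.6): carried by 13/20 samples (65%)
  recurrent amplification chr2:378859-551980 (penetrance 0.35): carried by 8/20 samples (40%)
```

and the recurrence step recovers both implanted regions from the calls
alone:

```
68 minimal common regions from 64 calls
recurrent gain regions (>=50%): 2
  chr1:629759-632267  50%
  chr1:632268-875641  55%
frequent amplification regions (>=20%): 1
  chr2:378859-551980  40%
```

i.e. the gain region is recurrent at 50–55% (its edges carry one-probe
breakpoint jitter, and two marginal carriers fall below the retention
threshold once private CNVs widen the normalization target), and the
amplification region is recovered at exactly its realized 40% carriage.
The qPCR validation step simulates the two reported group designs
(underlying fold changes 6.61 for GLI1, 26 tumors vs 14 controls, and
3.92 for GEFT, 33 vs 14) with 0.3-cycle replicate noise and recovers

```
GLI1: fold=6.22 (underlying 6.61), t=26.19, p=0.0000 (significant)
GEFT: fold=3.73 (underlying 3.92), t=23.08, p=0.0000 (significant)
```

The same stages are available as a CLI (`cnvseg simulate / preprocess /
segment / call / recur / annotate / enrich / qpcr / run`); `cnvseg run
--out-dir DIR` executes the full chain from one YAML config and writes
a machine-readable `summary.json` whose reruns are byte-identical for a
fixed config and seed.

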