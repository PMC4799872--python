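# panelcnv

Exon-resolution copy-number variant (CNV) detection from read depth for
targeted clinical gene panels, plus the cohort-level arithmetic needed to
report CNV prevalence — built around the regime of cardiomyopathy panel
diagnostics (46 genes, batches of 10 samples, ~200× exon coverage).

Molecular diagnostic labs sequencing gene panels historically reported only
SNVs and small indels; single- and multi-exon deletions/duplications fell
between molecular and cytogenomic testing. `panelcnv` implements the simple,
fully within-batch depth method used to close that gap, and a synthetic-cohort
simulator that lets every stage be validated against known truth.

## Method

For sample *s* and captured interval *t* with mean depth *d<sub>s,t</sub>*:

1. **Fractional coverage** removes library size:
   *f<sub>s,t</sub> = d<sub>s,t</sub> / Σ<sub>t′</sub> d<sub>s,t′</sub>*.
2. **Batch-median log2 ratio** removes capture efficiency:
   *r<sub>s,t</sub> = log₂(f<sub>s,t</sub> / median<sub>s′∈batch</sub> f<sub>s′,t</sub>)*,
   where the median for chrX/chrY targets is taken over same-sex batch
   samples only. On this scale 0 ≈ two copies, −1 a heterozygous loss,
   +0.585 one extra copy.
3. **Fixed-threshold calling**: a target is aberrant when
   *r ≥ +0.40* (gain) or *r ≤ −0.55* (loss), inclusive; maximal
   same-direction runs contiguous in genome order on one chromosome become
   calls (intragenic / whole-gene / multi-gene).
4. **Review**: loci called in ≥1% of cohort samples (≥2 carriers, ≥50%
   reciprocal overlap, same direction) are flagged as recurrent artifacts;
   remaining calls are scored against batch noise (signal ≥ 2×MAD of
   non-carrier samples over the call's targets).
5. **Classification** (simplified three tiers): losses in genes whose
   pathogenic spectrum is loss-of-function → P/LP; duplications → VUS
   (intragenic ones predicted LOF); artifact-frequency loci → benign.
6. **Cohort summary**: individual-level detection rates as exact fractions
   per phenotype and per gene.

## Worked example

```
python analysis/01_simulate_cohort.py --seed 17   # 100 samples, 300 targets
python analysis/02_call_and_review.py             # full pipeline + truth check
python analysis/03_benchmark_detection.py         # seeded benchmarks
python analysis/04_cohort_prevalence.py           # cohort rate arithmetic
```

which prints, among other things:

```
Pipeline made 22 raw calls: 18 pass, 4 artifact_freq, 0 low_quality.
Recovered 12/12 injected events with a pass-verdict, direction-correct call.

Spike-in sensitivity (seed 17): 100.0% overall (losses 248/248, gains 252/252);
exact boundaries 85.2%.
Null cohort: 0.045 false calls/sample before review.
Frequency filter: removed 74/74 artifact-locus calls, lost 0/32 true calls.

Individuals with >=1 clinically significant CNV: 9/1425 (0.63%)
Individuals with >=1 P_LP CNV: 4/1425 (0.28%)
Intragenic fraction of calls: 6/9
```

Reading this: all twelve spike-ins planted in the simulated cohort come back
as pass-verdict calls with the right direction, while every call at the two
planted recurrent (≥2% frequency) loci is flagged by the 1% cohort-frequency
filter. On the large benchmark, all 500 injected events are detected at seed
17; exact exon boundaries are recovered for every loss but only ~70% of gains,
because the +0.40 threshold sits just 0.185 below the +0.585 single-copy-gain
signal. The cohort numbers are the detection rates over the packaged
1425-patient cardiomyopathy cohort: CNVs are a real but small contributor
(0.63% of patients, 0.28% pathogenic/likely pathogenic, and 6 of the 9 events
are intragenic — invisible to conventional cytogenomic testing).

There is also a CLI (`panelcnv simulate | call | review | classify |
summarize | plot | run | benchmark`) wrapping the same library functions, e.g.

```
panelcnv run --targets sim/targets.bed --coverage sim/coverage.tsv \
    --samples sim/samples.tsv --out out/
```

## Layout

- `src/panelcnv/` — the library: `io` (BED/TSV model), `core`
  (normalization + calling), `review`, `classify`, `cohort`, `simulate`,
  `benchmark`, `pipeline`, `plotting`, `cli`.
- `src/panelcnv/data/` — packaged cohort tables (patient calls, gene
  disease-mechanism knowledge).
- `analysis/` — numbered narrative drivers writing under `results/`.
- `docs/methods.md` — model, parameters, numerical choices, limitations.
- `tests/` — pytest suite, including a brute-force segmentation oracle and
  seeded property tests.
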