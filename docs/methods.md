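# Methods

## Model and assumptions

`panelcnv` targets the depth regime of clinical targeted panels: a few
hundred exon-level capture intervals sequenced at ~200× mean depth in
small batches (default 10 samples) that are processed together. The
caller assumes that, within a batch, per-target mean depth factorizes as

    d[s, t] ≈ L_s · c_t · (n_{s,t} / 2) · ε_{s,t}

with a per-sample library factor `L_s`, a per-target capture efficiency
`c_t`, absolute copy number `n_{s,t}` (2 on autosomes, 1 on male X), and
multiplicative noise `ε`. Dividing each row by its total removes `L_s`
(fractional coverage); dividing each column by its batch median removes
`c_t`; the residual log2 ratio estimates `log2(n/baseline)`. The batch
is the only reference: no cross-batch panel of normals, no GC or
interval-length covariates, and no segmentation model — fixed inclusive
thresholds (+0.40 gain, −0.55 loss) with contiguity-based run merging.
This is appropriate exactly when batches are homogeneous in capture
chemistry and when at most one or two samples per batch carry a variant
at any locus (so the median is uncontaminated); the batch-size floor of
3 and the ≤1-carrier-per-batch assumption are where the method breaks
first.

### Sex chromosomes

X/Y targets are normalized within same-sex batch samples. Without this,
every male would sit at −1 on X (an apparent deletion) and a female
trisomy X (+log2(3/2) ≈ +0.585 versus the female median) would be
diluted by the male half of the batch. A sex stratum smaller than 3
samples is masked for those samples rather than mis-normalized; samples
of unknown sex are masked on X/Y. Masking is tracked per (sample,
target) because usability is stratum-dependent.

### Medians and exact centering

The per-target batch median is taken in log space; for even strata this
is the geometric mean of the two central order statistics. This makes
the stratum median of the resulting log2 ratios exactly zero (to
floating point), which the test suite asserts at 1e−9; an arithmetic
even-median would leave an O(noise²) offset. Odd strata are unaffected.

### Zero coverage

Fractional values and medians are floored at a pseudocount (default
1e−6 on the fractional scale) before the ratio, so capture dropouts
stay finite and surface as deep losses; a target whose stratum median
is at the floor is masked rather than called, preventing
whole-batch-dropout targets from producing spurious homozygous
deletions. Values above the floor are untouched, so library-size scale
invariance holds to rounding and noiseless ratios are exact.

### Denominator coupling

Because the fractional denominator is the sample's own total, a real
event perturbs it: an event covering a fraction *w* of the sample's
capture attenuates its own log2 ratio by log2(1 + (k/2 − 1)·w) for a
k-copy event. This is <0.01 for exon-scale events on a ≥300-target
panel but ≈0.04 for a whole-X trisomy with a 5% X capture share (the
expected X log2 is then ≈ +0.55 rather than +0.585 — still well above
the +0.40 gain threshold). The same coupling makes males' autosomal
fractions ~2% higher than females' in mixed batches (their X burns less
depth). Both effects are intrinsic to fractional-coverage
normalization, are far smaller than the calling margins, and are
covered by the tolerances in the noiseless tests.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `gain_min_log2` | +0.40 | inclusive gain threshold; 0.185 below the +0.585 single-extra-copy signal |
| `loss_max_log2` | −0.55 | inclusive loss threshold; 0.45 above the −1 heterozygous-loss signal |
| `pseudocount` | 1e−6 | fractional-scale floor; also the masking criterion for dead targets |
| `freq_cutoff` | 0.01 | cohort-frequency artifact cutoff (fraction of samples) |
| `noise_multiplier` | 2.0 | review rule: a call passes when signal ≥ multiplier × batch MAD |
| batch size | 10 | samples per normalization batch (minimum 3) |

## Review and classification

Two calls are "the same locus" when they share direction and ≥50%
reciprocal overlap in target space (the standard CNV convention); locus
carrier counts are accumulated cohort-wide by union-find. A locus is a
recurrent artifact when it has ≥2 distinct carriers and carrier
frequency ≥ 1% — the two-carrier floor keeps a single private call from
being "recurrent" in a small cohort. Filtered calls are annotated, never
dropped.

The review score is a deliberate quantitative surrogate for manual
inspection of per-sample plots: signal = |mean log2| of the call,
noise = median absolute deviation of the same targets across
non-carrier batch samples, verdict `low_quality` when signal < 2×noise.
The specificity gain of human review in the original diagnostic
workflow depended on reviewer judgment and patient data and is not
reproduced; instead the surrogate's behavior is pinned by simulation
(100% planted-artifact removal, 0% true-event loss at the default
settings, seeded).

Classification is a five-rule, three-tier scheme driven by per-gene
disease mechanism (packaged knowledge table): R1 artifact-frequency →
benign; R2 loss in a LOF-mechanism gene → P/LP; R3 loss otherwise →
VUS; R4 intragenic gain → VUS with predicted LOF outcome (most
intragenic duplications are tandem and frame-disrupting, but depth data
cannot exclude an insertional copy); R5 whole-gene/multi-gene gain →
VUS, outcome unknown. Pathogenic and likely pathogenic are not
distinguished — that split rests on segregation and prior-report
evidence outside this data model. Genes without a curated record
classify conservatively (mechanism unknown, so losses are VUS). The
`GOF` mechanism value is accepted but fires no rule.

## Cohort arithmetic

Rates are exact unreduced fractions; numerators count individuals
(a patient with two calls counts once) except the intragenic fraction,
which counts calls. VUS calls are included in "clinically significant"
rates, matching how the per-phenotype counts are tallied in the
packaged cohort table. Two internal inconsistencies of that source are
surfaced as notes rather than silently resolved: the ARVC denominator
(composition says 90; one narrative rate was printed against 99) and
the HCM rate (4/708 renders as 0.6%, not the 0.4% printed).

## The simulator

`simulate_cohort` draws `L_s` and `c_t` lognormal (natural-log sd 0.3
and 0.5), applies absolute copy states (events, recurrent
population-polymorphic artifact loci, sex-dependent X baseline), and
multiplies by `2^η`, `η ~ N(0, noise_sd)` with `noise_sd = 0.1` on the
log2 scale by default. Depth is proportional to absolute copies, so
expected post-normalization ratios are exactly `log2(copies/baseline)`
up to the denominator coupling above. One RNG stream, seed in the
config; identical seeds give bit-identical matrices and truth.

It does **not** model count-level (negative-binomial) noise, GC or
mapping bias, batch-to-batch chemistry drift, or read-level artifacts —
at ~200× the lognormal approximation is adequate and keeps expected
shifts analytic. Passing simulation tests therefore demonstrates the
arithmetic and the calling logic under the stated noise model, not
robustness to real-world capture pathologies.

Spike-in experiments place events on autosomal targets only: "copy 1
loss / copy 3 gain" is defined against the diploid baseline and would
be ambiguous on male X.

## Detection margins and problem sizes

At noise sd 0.10 the loss margin is |−1 − (−0.55)| = 0.45 (≈4σ even
after median-estimation noise), so heterozygous losses are detected
essentially always and with exact boundaries. The gain margin is only
0.585 − 0.40 = 0.185 (≈1.8σ): each gain target independently falls
below threshold with ~3–6% probability, so single-exon gains are
occasionally missed outright and multi-exon gains lose boundary exons
(~70% exact-boundary recovery) while remaining detected through their
other targets. Measured direction-correct sensitivity on 500 spike-ins
is 99.2–100% across seeds. At noise sd 0.15 the loss margin drops to
≈2.8σ and a few misses per 500 single-exon losses appear.

The standard benchmark sizes — 50 batches × 10 samples × ~500 targets
with 500 events, and a 500-sample artifact-filter cohort — run in
seconds and give ±1% resolution on the measured rates, which matches
the granularity of the claims being checked.

## Known limitations

- Within-batch normalization cannot see variants shared by most of a
  batch (e.g. a common polymorphic CNV hitting ≥5 of 10 samples shifts
  the median itself).
- Calls are defined on captured exons only; intronic or intergenic
  events, and any event in a masked target, are invisible.
- The classifier encodes mechanism knowledge for the packaged gene set
  only and deliberately implements no population-frequency lookup or
  segregation logic.
- The VCF output is minimal symbolic DEL/DUP records (END,
  FOLD_CHANGE); breakpoints are exon-resolution by construction.
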