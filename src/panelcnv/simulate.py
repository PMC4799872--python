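"""Synthetic cohorts with known copy-number truth.

The generator emulates the statistical regime of a targeted clinical
panel sequenced in batches: a few hundred exon-level targets (including
a block of X-linked genes), per-target capture efficiency spread over
roughly an order of magnitude (lognormal, sd 0.5 natural-log), per-sample
library-size variation, multiplicative lognormal depth noise, recurrent
polymorphic artifact loci, sex-dependent X copy states, and injected
CNV events of known span and copy number:

    depth[s, t] = depth_mean * lib_s * cap_t * (copies[s, t] / 2) * 2**eta,
    eta ~ Normal(0, noise_sd)

Depth is proportional to absolute copy number (a male X target carries
one copy, hence half the depth of a female's), so expected log2 ratios
after sex-aware batch normalization are exactly log2(copies / baseline).
No read-level, GC, or mapping-bias effects are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import (
    CoverageMatrix,
    SampleMeta,
    TargetInterval,
    TargetSet,
    ValidationError,
)

_EVENT_KINDS = ("single_exon", "multi_exon", "whole_gene", "whole_chromosome")


@dataclass(frozen=True)
class SimEvent:
    """One injected copy-number event.

    ``first_target``/``last_target`` are inclusive genome-order bounds;
    ``copy_number`` is the absolute copy count (diploid autosomal
    baseline 2, male X baseline 1).
    """

    sample_index: int
    first_target: int
    last_target: int
    copy_number: int
    kind: str = "multi_exon"
    source: str = "injected"  # 'injected' | 'artifact'

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValidationError("copy_number must be >= 0")
        if self.first_target > self.last_target:
            raise ValidationError("event span is empty")
        if self.kind not in _EVENT_KINDS:
            raise ValidationError(f"kind must be one of {_EVENT_KINDS}")

    @property
    def n_targets(self) -> int:
        return self.last_target - self.first_target + 1

    def expected_log2(self, baseline: int = 2) -> float:
        """Expected post-normalization log2 ratio, log2(copies/baseline)."""
        if self.copy_number == 0:
            return float("-inf")
        return float(np.log2(self.copy_number / baseline))


@dataclass(frozen=True)
class ArtifactLocus:
    """A recurrent, population-polymorphic copy state (the raw material
    of the >=1% cohort-frequency filter)."""

    first_target: int
    last_target: int
    frequency: float
    copy_number: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValidationError("frequency must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the clinical regime the caller targets: batches of
    10 samples, ~200x mean exon depth, lognormal capture efficiency
    (sd 0.5, natural log), lognormal library size (sd 0.3, natural
    log), and multiplicative depth noise of sd 0.1 on the log2 scale.
    """

    n_batches: int = 1
    batch_size: int = 10
    n_targets: int = 100
    target_effect_sd: float = 0.5
    depth_mean: float = 200.0
    library_sd: float = 0.3
    noise_sd: float = 0.1
    sex_ratio: float = 0.5
    artifact_loci: tuple[ArtifactLocus, ...] = ()
    events: tuple[SimEvent, ...] = ()
    seed: int = 17

    def __post_init__(self) -> None:
        if min(self.n_batches, self.batch_size, self.n_targets) < 1:
            raise ValidationError("counts must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValidationError("sex_ratio must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_batches * self.batch_size


# Gene names of the X-linked block included in every synthetic panel,
# mirroring a cardiomyopathy panel's X-chromosome content.
X_GENES = ("GLA", "LAMP2", "EMD", "TAZ")
_EXON_CYCLE = (4, 7, 3, 10, 5, 8, 6, 12)
_EXON_LEN = 150
_EXON_GAP = 2000
_GENE_GAP = 50_000


def synthetic_targets(
    n_targets: int, x_fraction: float = 0.05
) -> TargetSet:
    """Build a synthetic exon-level panel of ``n_targets`` intervals.

    Autosomal genes (cycling exon counts of 3-12) are distributed over
    chromosomes 1-22; roughly ``x_fraction`` of targets form four
    X-linked genes appended on chrX, so sex-aware normalization always
    has work to do.
    """
    if n_targets < 8:
        raise ValidationError("need at least 8 targets for a synthetic panel")
    n_x = max(4, int(round(n_targets * x_fraction)))
    n_auto = n_targets - n_x
    intervals: list[TargetInterval] = []

    def add_gene(chrom: str, gene: str, n_exons: int, start: int) -> int:
        pos = start
        for e in range(1, n_exons + 1):
            intervals.append(
                TargetInterval(
                    chrom, pos, pos + _EXON_LEN, gene, f"{gene}_ex{e}", 0
                )
            )
            pos += _EXON_LEN + _EXON_GAP
        return pos + _GENE_GAP

    made = 0
    gi = 0
    chrom_pos: dict[str, int] = {}
    while made < n_auto:
        n_exons = min(_EXON_CYCLE[gi % len(_EXON_CYCLE)], n_auto - made)
        chrom = f"chr{(gi % 22) + 1}"
        gene = f"GENE{gi + 1:03d}"
        chrom_pos[chrom] = add_gene(
            chrom, gene, n_exons, chrom_pos.get(chrom, 10_000)
        )
        made += n_exons
        gi += 1

    # split the X block across the four canonical X genes
    per = [n_x // 4] * 4
    for i in range(n_x % 4):
        per[i] += 1
    pos = 10_000
    for gene, n_exons in zip(X_GENES, per):
        if n_exons:
            pos = add_gene("chrX", gene, n_exons, pos)

    return TargetSet(intervals)


def _baselines(targets: TargetSet, samples: Sequence[SampleMeta]) -> np.ndarray:
    """Baseline copy count per (sample, target): 2 everywhere except
    male X (1).  chrY targets are not generated by synthetic panels."""
    base = np.full((len(samples), len(targets)), 2, dtype=np.int64)
    is_x = np.array([t.chrom in ("chrX", "X") for t in targets])
    for i, m in enumerate(samples):
        if m.sex == "male":
            base[i, is_x] = 1
    return base


_PHENO_POOL = ("HCM", "DCM", "ARVC", "LVNC", "RCM", "NOS", "other")
_PHENO_WEIGHTS = (708, 479, 90, 54, 25, 61, 8)


def simulate_cohort(
    cfg: SimConfig, targets: TargetSet | None = None
) -> tuple[CoverageMatrix, list[SimEvent]]:
    """Simulate a batched coverage matrix plus its copy-number truth.

    Returns the matrix and all true copy-state departures from
    baseline: the configured events (``source='injected'``) plus the
    per-sample realizations of the artifact loci
    (``source='artifact'``).  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    if targets is None:
        targets = synthetic_targets(cfg.n_targets)
    n_t = len(targets)
    if n_t != cfg.n_targets:
        cfg = replace(cfg, n_targets=n_t)

    samples = []
    weights = np.array(_PHENO_WEIGHTS, dtype=float)
    weights /= weights.sum()
    for b in range(cfg.n_batches):
        for i in range(cfg.batch_size):
            sex = "female" if rng.random() < cfg.sex_ratio else "male"
            phen = str(rng.choice(_PHENO_POOL, p=weights))
            samples.append(
                SampleMeta(
                    sample_id=f"S{b:03d}_{i:02d}",
                    batch_id=f"B{b:03d}",
                    sex=sex,
                    phenotype=phen,
                )
            )
    n_s = len(samples)

    copies = _baselines(targets, samples).astype(float)
    truth: list[SimEvent] = []

    for locus in cfg.artifact_loci:
        if locus.last_target >= n_t:
            raise ValidationError("artifact locus span exceeds target count")
        carriers = np.flatnonzero(rng.random(n_s) < locus.frequency)
        for s in carriers:
            copies[s, locus.first_target : locus.last_target + 1] = (
                locus.copy_number
            )
            truth.append(
                SimEvent(
                    sample_index=int(s),
                    first_target=locus.first_target,
                    last_target=locus.last_target,
                    copy_number=locus.copy_number,
                    kind=(
                        "single_exon"
                        if locus.first_target == locus.last_target
                        else "multi_exon"
                    ),
                    source="artifact",
                )
            )

    occupied: set[tuple[int, int]] = {
        (e.sample_index, t)
        for e in truth
        for t in range(e.first_target, e.last_target + 1)
    }
    for ev in cfg.events:
        if ev.last_target >= n_t:
            raise ValidationError(
                f"event span {ev.first_target}-{ev.last_target} exceeds "
                f"{n_t} targets"
            )
        span = {(ev.sample_index, t) for t in range(ev.first_target, ev.last_target + 1)}
        if span & occupied:
            raise ValidationError(
                f"event overlaps a prior event in sample {ev.sample_index}"
            )
        occupied |= span
        copies[ev.sample_index, ev.first_target : ev.last_target + 1] = (
            ev.copy_number
        )
        truth.append(ev)

    lib = np.exp(rng.normal(0.0, cfg.library_sd, size=n_s))
    cap = np.exp(rng.normal(0.0, cfg.target_effect_sd, size=n_t))
    depth = cfg.depth_mean * lib[:, None] * cap[None, :] * (copies / 2.0)
    if cfg.noise_sd > 0:
        depth = depth * np.exp2(rng.normal(0.0, cfg.noise_sd, size=(n_s, n_t)))

    return CoverageMatrix(targets, samples, depth), truth


def inject_event(
    matrix: CoverageMatrix,
    event: SimEvent,
    existing: Sequence[SimEvent] = (),
) -> CoverageMatrix:
    """Scale the affected cells of a coverage matrix by
    copy_number / baseline; every other cell is bit-identical.

    ``existing`` events guard against double-injection: overlapping a
    prior event on the same sample is an error.
    """
    if event.last_target >= len(matrix.targets):
        raise ValidationError("event span exceeds target count")
    for prior in existing:
        if prior.sample_index == event.sample_index and not (
            event.last_target < prior.first_target
            or event.first_target > prior.last_target
        ):
            raise ValidationError(
                f"event overlaps a prior event in sample {event.sample_index}"
            )
    base = _baselines(matrix.targets, matrix.samples)
    depth = matrix.depth.copy()
    s = event.sample_index
    sl = slice(event.first_target, event.last_target + 1)
    depth[s, sl] = depth[s, sl] * (event.copy_number / base[s, sl])
    return CoverageMatrix(matrix.targets, matrix.samples, depth)


def write_truth_tsv(
    truth: Sequence[SimEvent],
    matrix: CoverageMatrix,
    path,
) -> None:
    """Write the truth set as BED-like TSV with genomic coordinates."""
    targets = matrix.targets
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "sample_id\tchrom\tstart\tend\tfirst_target\tlast_target\t"
            "copy_number\tkind\tsource\n"
        )
        for e in truth:
            t0, t1 = targets[e.first_target], targets[e.last_target]
            fh.write(
                f"{matrix.samples[e.sample_index].sample_id}\t{t0.chrom}\t"
                f"{t0.start}\t{t1.end}\t{e.first_target}\t{e.last_target}\t"
                f"{e.copy_number}\t{e.kind}\t{e.source}\n"
            )
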