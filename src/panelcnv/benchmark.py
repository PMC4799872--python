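"""Simulation experiments validating the calling pipeline.

Each experiment builds synthetic cohorts with known truth, runs the
exact production code path (fractional coverage -> batch-median log2
ratios -> threshold calling -> review), and measures performance
against the truth.  These functions power the acceptance checks and
the analysis drivers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CnvCall, Thresholds, call_segments, fractional_coverage, log2_ratios
from .io import CoverageMatrix, TargetSet, ValidationError
from .review import frequency_filter
from .simulate import ArtifactLocus, SimConfig, SimEvent, simulate_cohort, synthetic_targets


def _autosomal_blocks(targets: TargetSet) -> list[tuple[int, int]]:
    """Maximal genome-order runs of autosomal targets on one chromosome
    (inclusive bounds) — the placements where a contiguous event can
    surface as a single call."""
    blocks = []
    start = None
    for j in range(len(targets)):
        if targets.is_sex_chrom[j]:
            if start is not None:
                blocks.append((start, j - 1))
                start = None
            continue
        if start is None:
            start = j
        elif targets.chroms[j] != targets.chroms[j - 1]:
            blocks.append((start, j - 1))
            start = j
    if start is not None:
        blocks.append((start, len(targets) - 1))
    return blocks


def _place_events(
    rng: np.random.Generator,
    targets: TargetSet,
    n_batches: int,
    batch_size: int,
    n_events: int,
    span_range: tuple[int, int],
    gain_copy: int = 3,
    loss_copy: int = 1,
) -> list[SimEvent]:
    """Assign at most one event per sample, with disjoint spans within a
    batch so no locus has more than one carrier per batch."""
    if n_events > n_batches * batch_size:
        raise ValidationError("more events than samples")
    blocks = _autosomal_blocks(targets)
    lo, hi = span_range
    events: list[SimEvent] = []
    used: dict[int, set[int]] = {b: set() for b in range(n_batches)}
    order = [(b, i) for b in range(n_batches) for i in range(batch_size)]
    for b, i in order[:n_events]:
        sample_index = b * batch_size + i
        for _ in range(1000):
            span = int(rng.integers(lo, hi + 1))
            bs, be = blocks[int(rng.integers(0, len(blocks)))]
            if be - bs + 1 < span:
                continue
            first = int(rng.integers(bs, be - span + 2))
            cells = set(range(first, first + span))
            if cells & used[b]:
                continue
            used[b] |= cells
            copy = gain_copy if rng.random() < 0.5 else loss_copy
            events.append(
                SimEvent(
                    sample_index=sample_index,
                    first_target=first,
                    last_target=first + span - 1,
                    copy_number=copy,
                    kind="single_exon" if span == 1 else "multi_exon",
                )
            )
            break
        else:  # pragma: no cover - only with absurdly dense configs
            raise ValidationError("could not place event without overlap")
    return events


def _call_cohort(
    matrix: CoverageMatrix, thresholds: Thresholds
) -> list[CnvCall]:
    calls: list[CnvCall] = []
    for batch_id in matrix.batch_ids:
        sub = matrix.subset_batch(batch_id)
        l2m = log2_ratios(fractional_coverage(sub), thresholds)
        calls.extend(call_segments(l2m, thresholds))
    return calls


def _overlaps(call: CnvCall, ev: SimEvent) -> bool:
    return not (
        call.last_target < ev.first_target or call.first_target > ev.last_target
    )


@dataclass(frozen=True)
class SensitivityResult:
    n_events: int
    n_detected: int
    n_exact_span: int
    n_loss: int
    n_loss_detected: int
    n_gain: int
    n_gain_detected: int
    n_false_calls: int
    n_samples: int

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_events

    @property
    def exact_span_rate(self) -> float:
        return self.n_exact_span / self.n_events


def sensitivity_experiment(
    n_batches: int = 50,
    batch_size: int = 10,
    n_targets: int = 500,
    n_events: int = 500,
    noise_sd: float = 0.1,
    span_range: tuple[int, int] = (1, 10),
    seed: int = 17,
    thresholds: Thresholds | None = None,
) -> SensitivityResult:
    """Spike-in recovery under the caller's intended regime.

    Injects heterozygous losses (copy 1) and single-copy gains (copy 3)
    of 1-10 contiguous autosomal targets, at most one carrier per batch
    per locus, then measures the fraction recovered by a same-direction
    overlapping call (sensitivity) and by an exact-boundary call.
    """
    thresholds = thresholds or Thresholds()
    rng = np.random.default_rng(seed)
    targets = synthetic_targets(n_targets)
    events = _place_events(
        rng, targets, n_batches, batch_size, n_events, span_range
    )
    cfg = SimConfig(
        n_batches=n_batches,
        batch_size=batch_size,
        n_targets=len(targets),
        noise_sd=noise_sd,
        events=tuple(events),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    matrix, truth = simulate_cohort(cfg, targets=targets)
    calls = _call_cohort(matrix, thresholds)

    by_sample: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)

    injected = [e for e in truth if e.source == "injected"]
    n_det = n_exact = 0
    n_loss = n_loss_det = n_gain = n_gain_det = 0
    matched_calls: set[int] = set()
    for ev in injected:
        sid = matrix.samples[ev.sample_index].sample_id
        want = "loss" if ev.copy_number < 2 else "gain"
        if want == "loss":
            n_loss += 1
        else:
            n_gain += 1
        hits = [
            c
            for c in by_sample.get(sid, [])
            if c.direction == want and _overlaps(c, ev)
        ]
        if hits:
            n_det += 1
            if want == "loss":
                n_loss_det += 1
            else:
                n_gain_det += 1
            matched_calls.update(id(c) for c in hits)
            if any(
                c.first_target == ev.first_target
                and c.last_target == ev.last_target
                for c in hits
            ):
                n_exact += 1
    n_false = sum(1 for c in calls if id(c) not in matched_calls)
    return SensitivityResult(
        n_events=len(injected),
        n_detected=n_det,
        n_exact_span=n_exact,
        n_loss=n_loss,
        n_loss_detected=n_loss_det,
        n_gain=n_gain,
        n_gain_detected=n_gain_det,
        n_false_calls=n_false,
        n_samples=cfg.n_samples,
    )


def null_false_call_rate(
    n_batches: int = 20,
    batch_size: int = 10,
    n_targets: int = 500,
    noise_sd: float = 0.1,
    seed: int = 17,
    thresholds: Thresholds | None = None,
) -> float:
    """Calls per sample on an event-free cohort (pre-review)."""
    thresholds = thresholds or Thresholds()
    cfg = SimConfig(
        n_batches=n_batches,
        batch_size=batch_size,
        n_targets=n_targets,
        noise_sd=noise_sd,
        seed=seed,
    )
    matrix, _ = simulate_cohort(cfg)
    calls = _call_cohort(matrix, thresholds)
    return len(calls) / cfg.n_samples


@dataclass(frozen=True)
class ArtifactFilterResult:
    n_artifact_calls: int
    n_artifact_flagged: int
    n_true_calls: int
    n_true_flagged: int
    n_other_calls: int

    @property
    def artifact_removal_rate(self) -> float:
        return self.n_artifact_flagged / self.n_artifact_calls

    @property
    def true_loss_rate(self) -> float:
        return self.n_true_flagged / self.n_true_calls


def artifact_filter_experiment(
    n_batches: int = 50,
    batch_size: int = 10,
    n_targets: int = 200,
    n_true_events: int = 30,
    noise_sd: float = 0.1,
    freq_cutoff: float = 0.01,
    seed: int = 17,
    thresholds: Thresholds | None = None,
) -> ArtifactFilterResult:
    """Planted recurrent artifact loci vs private true events.

    Three polymorphic loci at 2-5% population frequency are planted
    alongside private single-carrier events placed away from them; the
    cohort-frequency filter should flag every artifact-locus call and
    no private true-event call.
    """
    thresholds = thresholds or Thresholds()
    rng = np.random.default_rng(seed)
    targets = synthetic_targets(n_targets)
    artifact_loci = (
        ArtifactLocus(10, 11, 0.05, copy_number=3),
        ArtifactLocus(60, 60, 0.03, copy_number=1),
        ArtifactLocus(120, 123, 0.02, copy_number=3),
    )
    artifact_cells = {
        t
        for loc in artifact_loci
        for t in range(loc.first_target, loc.last_target + 1)
    }
    events = []
    placed = _place_events(
        rng, targets, n_batches, batch_size, n_true_events * 3, (1, 6)
    )
    for ev in placed:
        cells = set(range(ev.first_target, ev.last_target + 1))
        if cells & artifact_cells:
            continue
        events.append(ev)
        if len(events) == n_true_events:
            break
    cfg = SimConfig(
        n_batches=n_batches,
        batch_size=batch_size,
        n_targets=len(targets),
        noise_sd=noise_sd,
        artifact_loci=artifact_loci,
        events=tuple(events),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    matrix, truth = simulate_cohort(cfg, targets=targets)
    calls = _call_cohort(matrix, thresholds)
    filtered = frequency_filter(calls, cfg.n_samples, freq_cutoff)

    truth_by_sample: dict[str, list[SimEvent]] = {}
    for e in truth:
        sid = matrix.samples[e.sample_index].sample_id
        truth_by_sample.setdefault(sid, []).append(e)

    na = naf = nt = ntf = nother = 0
    for call, _freq, flagged in filtered:
        kinds = {
            e.source
            for e in truth_by_sample.get(call.sample_id, [])
            if _overlaps(call, e)
        }
        if "artifact" in kinds:
            na += 1
            naf += flagged
        elif "injected" in kinds:
            nt += 1
            ntf += flagged
        else:
            nother += 1
    return ArtifactFilterResult(na, naf, nt, ntf, nother)
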