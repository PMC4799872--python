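"""Shared fixtures and the independent brute-force calling oracle."""

from __future__ import annotations

import numpy as np
import pytest

from panelcnv.core import CnvCall, Log2RatioMatrix, Thresholds
from panelcnv.io import SampleMeta, TargetInterval, TargetSet


def make_targets(spec: list[tuple[str, str, int]]) -> TargetSet:
    """Build a TargetSet from (chrom, gene, n_exons) triples, laid out
    left to right with non-overlapping coordinates."""
    intervals = []
    pos: dict[str, int] = {}
    for chrom, gene, n_exons in spec:
        p = pos.get(chrom, 1000)
        for e in range(1, n_exons + 1):
            intervals.append(
                TargetInterval(chrom, p, p + 100, gene, f"{gene}_ex{e}", 0)
            )
            p += 1000
        pos[chrom] = p + 10_000
    return TargetSet(intervals)


def make_samples(n: int, batch: str = "B0", sex: str = "female") -> list[SampleMeta]:
    return [SampleMeta(f"{batch}_S{i:02d}", batch, sex=sex) for i in range(n)]


def make_l2m(
    targets: TargetSet,
    values: np.ndarray,
    mask: np.ndarray | None = None,
    sex: str = "female",
) -> Log2RatioMatrix:
    """Wrap a raw log2 matrix for direct segmentation tests."""
    values = np.asarray(values, dtype=float)
    samples = make_samples(values.shape[0], sex=sex)
    if mask is None:
        mask = np.zeros(values.shape, dtype=bool)
    return Log2RatioMatrix(targets, samples, values, mask)


def brute_force_calls(l2m: Log2RatioMatrix, thresholds: Thresholds) -> set:
    """Exhaustive per-target scan + naive run merge, written independently
    of the production path; returns comparable call keys."""
    out = set()
    for i, meta in enumerate(l2m.samples):
        labels = []
        for j in range(len(l2m.targets)):
            v = l2m.log2ratio[i, j]
            if l2m.mask[i, j] or not np.isfinite(v):
                labels.append("masked")
            elif v >= thresholds.gain_min_log2:
                labels.append("gain")
            elif v <= thresholds.loss_max_log2:
                labels.append("loss")
            else:
                labels.append("normal")
        j = 0
        while j < len(labels):
            if labels[j] not in ("gain", "loss"):
                j += 1
                continue
            k = j
            while (
                k + 1 < len(labels)
                and labels[k + 1] == labels[j]
                and l2m.targets.chroms[k + 1] == l2m.targets.chroms[k]
            ):
                k += 1
            out.add((meta.sample_id, j, k, labels[j]))
            j = k + 1
    return out


def call_keys(calls: list[CnvCall]) -> set:
    return {
        (c.sample_id, c.first_target, c.last_target, c.direction)
        for c in calls
    }


def make_call(
    sample_id: str = "S0",
    first: int = 0,
    last: int = 0,
    direction: str = "loss",
    mean_log2: float = -1.0,
    genes: tuple[str, ...] = ("GENE1",),
    span_kind: str = "intragenic",
    chrom: str = "chr1",
) -> CnvCall:
    return CnvCall(
        sample_id=sample_id,
        chrom=chrom,
        start=first * 1000,
        end=last * 1000 + 100,
        genes=genes,
        first_target=first,
        last_target=last,
        direction=direction,
        mean_log2=mean_log2,
        per_target_log2=tuple([mean_log2] * (last - first + 1)),
        span_kind=span_kind,
    )


@pytest.fixture
def small_targets() -> TargetSet:
    return make_targets(
        [("chr1", "GENEA", 5), ("chr1", "GENEB", 3), ("chr2", "GENEC", 4)]
    )
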