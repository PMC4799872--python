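"""Post-calling review: cohort-frequency artifact filtering and a
quantitative review score.

Clinical depth-based callers accumulate recurrent false calls at loci
with systematically unstable capture.  Two defenses are applied here:

* a cohort-frequency filter that flags loci called in at least 1% of
  cohort samples as presumed artifacts or benign polymorphisms, and
* a per-call review score comparing call signal (|mean log2|) to batch
  noise (MAD of the same targets across non-carrier batch samples),
  a quantitative surrogate for manual plot review.

Filtered calls are never dropped, only annotated with a verdict, so the
filtering is auditable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CnvCall, Log2RatioMatrix
from .io import PanelCnvError, ValidationError

DEFAULT_FREQ_CUTOFF = 0.01
DEFAULT_NOISE_MULTIPLIER = 2.0

VERDICTS = ("pass", "artifact_freq", "low_quality")


@dataclass(frozen=True)
class ReviewScore:
    """Quality metrics and verdict for one call."""

    call: CnvCall
    cohort_freq: float
    batch_noise: float
    signal: float
    n_targets: int
    verdict: str


def same_locus(a: CnvCall, b: CnvCall) -> bool:
    """Same-locus test: same direction and >=50% reciprocal target overlap."""
    if a.direction != b.direction or a.chrom != b.chrom:
        return False
    ov = min(a.last_target, b.last_target) - max(a.first_target, b.first_target) + 1
    if ov <= 0:
        return False
    return ov / a.n_targets >= 0.5 and ov / b.n_targets >= 0.5


def _locus_components(calls: Sequence[CnvCall]) -> list[int]:
    """Union-find over the same-locus relation; returns a component id
    per call, deterministic and independent of input order up to
    relabeling."""
    n = len(calls)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if same_locus(calls[i], calls[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    return [find(i) for i in range(n)]


def locus_frequencies(
    calls: Sequence[CnvCall], n_samples: int
) -> list[tuple[int, float]]:
    """Carrier count and frequency of each call's locus (distinct
    carrier samples in its same-locus component over cohort size)."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    comp = _locus_components(calls)
    carriers: dict[int, set[str]] = {}
    for c, call in zip(comp, calls):
        carriers.setdefault(c, set()).add(call.sample_id)
    return [(len(carriers[c]), len(carriers[c]) / n_samples) for c in comp]


def frequency_filter(
    calls: Sequence[CnvCall],
    n_samples: int,
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
) -> list[tuple[CnvCall, float, bool]]:
    """Partition cohort calls into artifact-frequency loci and the rest.

    Two calls belong to the same locus when they have the same direction
    and at least 50% reciprocal target overlap.  A locus is flagged as a
    recurrent artifact when it has at least two distinct carriers and
    carrier count / ``n_samples`` >= ``freq_cutoff`` (a single private
    call is never "recurrent", whatever the cohort size).  Returns
    ``(call, cohort_freq, is_artifact)`` in input order; the partition
    itself is order-independent.
    """
    freqs = locus_frequencies(calls, n_samples)
    return [
        (call, f, n >= 2 and f >= freq_cutoff)
        for call, (n, f) in zip(calls, freqs)
    ]


def review_score(
    call: CnvCall,
    l2m: Log2RatioMatrix,
    cohort_calls: Sequence[CnvCall],
    n_samples: int,
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF,
    noise_multiplier: float = DEFAULT_NOISE_MULTIPLIER,
) -> ReviewScore:
    """Score one call against its batch and the cohort.

    ``batch_noise`` is the median absolute deviation of the call's
    target log2 ratios across non-carrier batch samples (samples with a
    same-locus call, including the carrier, are excluded).  ``signal``
    is |mean log2| of the call.  Verdict precedence:
    artifact_freq > low_quality > pass, where low_quality means
    signal < noise_multiplier x batch_noise.
    """
    cols = range(call.first_target, call.last_target + 1)
    if call.last_target >= len(l2m.targets):
        raise PanelCnvError(
            f"call targets {call.first_target}-{call.last_target} not in "
            f"log2 matrix with {len(l2m.targets)} targets"
        )
    try:
        l2m.sample_index(call.sample_id)
    except KeyError as exc:
        raise PanelCnvError(
            f"call sample {call.sample_id!r} absent from log2 matrix"
        ) from exc

    pool = list(cohort_calls)
    if not any(c is call for c in pool):
        pool.append(call)
    freqs = locus_frequencies(pool, n_samples)
    n_carriers, freq = next(nf for c, nf in zip(pool, freqs) if c is call)

    carrier_ids = {
        c.sample_id for c in pool if same_locus(c, call)
    } | {call.sample_id}
    rows = [
        i for i, m in enumerate(l2m.samples) if m.sample_id not in carrier_ids
    ]
    col_idx = np.array(list(cols))
    values = l2m.log2ratio[np.ix_(rows, col_idx)] if rows else np.empty((0, 0))
    values = values[np.isfinite(values)] if values.size else values
    if values.size:
        med = np.median(values)
        noise = float(np.median(np.abs(values - med)))
    else:
        noise = float("nan")

    signal = abs(call.mean_log2)
    if n_carriers >= 2 and freq >= freq_cutoff:
        verdict = "artifact_freq"
    elif np.isfinite(noise) and signal < noise_multiplier * noise:
        verdict = "low_quality"
    else:
        verdict = "pass"
    return ReviewScore(
        call=call,
        cohort_freq=freq,
        batch_noise=noise,
        signal=signal,
        n_targets=call.n_targets,
        verdict=verdict,
    )
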