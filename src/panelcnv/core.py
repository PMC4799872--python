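"""Within-batch depth normalization and threshold-based CNV calling.

The method is deliberately simple and fully within-batch:

1. *Fractional coverage*: each sample's per-interval mean depth is
   divided by that sample's summed depth over all targets, cancelling
   library size.
2. *log2 ratio*: each fractional value is divided by the per-target
   median across the batch (same-sex samples only for X/Y targets) and
   log2-transformed, cancelling per-target capture efficiency.  On this
   scale 0 means two copies (autosome), -1 a heterozygous loss and
   +0.585 one extra copy.
3. *Calling*: fixed inclusive thresholds (gain >= +0.40,
   loss <= -0.55) flag aberrant targets; maximal same-direction runs
   contiguous in genome order on one chromosome become calls.

There is no segmentation model, GC correction, or cross-batch
reference: the batch itself is the reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    CoverageMatrix,
    SampleMeta,
    TargetSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

MIN_BATCH_SAMPLES = 3
MIN_STRATUM_SAMPLES = 3


@dataclass(frozen=True)
class Thresholds:
    """Fixed log2-ratio calling thresholds.

    Parameters
    ----------
    gain_min_log2
        Minimum log2 ratio for a gain call (inclusive).  +0.40 sits
        below the +0.585 expected for a single extra copy.
    loss_max_log2
        Maximum log2 ratio for a loss call (inclusive).  -0.55 sits
        above the -1 expected for a heterozygous loss.
    pseudocount
        Floor applied to fractional-coverage values and batch medians
        before forming ratios, so zero-coverage targets stay finite
        (they surface as deep losses).  Targets whose stratum median is
        at or below the floor are masked instead of called.
    """

    gain_min_log2: float = 0.40
    loss_max_log2: float = -0.55
    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        if not (self.gain_min_log2 > 0 > self.loss_max_log2):
            raise ValidationError(
                "thresholds must satisfy gain_min_log2 > 0 > loss_max_log2"
            )
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")


@dataclass
class FractionalMatrix:
    """Per-sample fractional coverage; every row sums to 1."""

    targets: TargetSet
    samples: list[SampleMeta]
    frac: np.ndarray


def fractional_coverage(matrix: CoverageMatrix) -> FractionalMatrix:
    """Divide each sample's depths by its total depth over all targets."""
    totals = matrix.depth.sum(axis=1)
    dead = np.flatnonzero(totals <= 0)
    if dead.size:
        names = [matrix.samples[i].sample_id for i in dead]
        raise ValidationError(f"samples with zero total depth: {names}")
    frac = matrix.depth / totals[:, None]
    return FractionalMatrix(matrix.targets, list(matrix.samples), frac)


@dataclass
class Log2RatioMatrix:
    """Batch-median-normalized log2 copy ratios for one batch.

    ``mask`` is samples x targets; a masked cell had no usable
    normalization stratum (median at the pseudocount floor, or fewer
    than 3 same-sex samples for an X/Y target) and carries no calls.
    Masked cells hold NaN.
    """

    targets: TargetSet
    samples: list[SampleMeta]
    log2ratio: np.ndarray
    mask: np.ndarray

    @property
    def masked_targets(self) -> np.ndarray:
        """Targets masked for every sample in the batch."""
        return self.mask.all(axis=0)

    def sample_index(self, sample_id: str) -> int:
        for i, m in enumerate(self.samples):
            if m.sample_id == sample_id:
                return i
        raise KeyError(sample_id)


def log2_ratios(
    frac: FractionalMatrix, thresholds: Thresholds | None = None
) -> Log2RatioMatrix:
    """Normalize one batch of fractional coverage to log2 copy ratios.

    Autosomal targets are normalized against the per-target median over
    all batch samples; X/Y targets against same-sex samples only, so a
    male X (one copy) is not half a female X.  The per-target median is
    taken in log space (geometric mean of the two central order
    statistics when the stratum count is even), which makes the stratum
    median of the resulting log2 ratios exactly zero.
    """
    thresholds = thresholds or Thresholds()
    n_samples, n_targets = frac.frac.shape
    if n_samples < MIN_BATCH_SAMPLES:
        raise ValidationError(
            f"batch has {n_samples} samples; at least "
            f"{MIN_BATCH_SAMPLES} are required for median normalization"
        )
    eps = thresholds.pseudocount
    logf = np.log2(np.maximum(frac.frac, eps))
    log_eps = math.log2(eps)

    ratio = np.full((n_samples, n_targets), np.nan)
    mask = np.zeros((n_samples, n_targets), dtype=bool)

    sexes = np.array([m.sex for m in frac.samples])
    is_sex_t = frac.targets.is_sex_chrom
    auto_cols = np.flatnonzero(~is_sex_t)
    sex_cols = np.flatnonzero(is_sex_t)

    if auto_cols.size:
        center = np.median(logf[:, auto_cols], axis=0)
        ratio[:, auto_cols] = logf[:, auto_cols] - center[None, :]
        degenerate = center <= log_eps
        if degenerate.any():
            mask[:, auto_cols[degenerate]] = True
            ratio[:, auto_cols[degenerate]] = np.nan

    if sex_cols.size:
        for sex in ("female", "male"):
            rows = np.flatnonzero(sexes == sex)
            if rows.size == 0:
                continue
            if rows.size < MIN_STRATUM_SAMPLES:
                logger.warning(
                    "only %d %s sample(s) in batch: sex-chromosome targets "
                    "masked for them",
                    rows.size,
                    sex,
                )
                mask[np.ix_(rows, sex_cols)] = True
                continue
            center = np.median(logf[np.ix_(rows, sex_cols)], axis=0)
            ratio[np.ix_(rows, sex_cols)] = (
                logf[np.ix_(rows, sex_cols)] - center[None, :]
            )
            degenerate = center <= log_eps
            if degenerate.any():
                mask[np.ix_(rows, sex_cols[degenerate])] = True
                ratio[np.ix_(rows, sex_cols[degenerate])] = np.nan
        unknown_rows = np.flatnonzero(sexes == "unknown")
        if unknown_rows.size:
            logger.warning(
                "%d sample(s) with unknown sex: sex-chromosome targets masked",
                unknown_rows.size,
            )
            mask[np.ix_(unknown_rows, sex_cols)] = True

    return Log2RatioMatrix(frac.targets, list(frac.samples), ratio, mask)


@dataclass(frozen=True)
class CnvCall:
    """A maximal run of same-direction aberrant targets in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    genes: tuple[str, ...]
    first_target: int
    last_target: int
    direction: str  # 'loss' | 'gain'
    mean_log2: float
    per_target_log2: tuple[float, ...]
    span_kind: str  # 'intragenic' | 'whole_gene' | 'multi_gene'
    exon_span: str = ""

    @property
    def n_targets(self) -> int:
        return self.last_target - self.first_target + 1


def _span_kind(targets: TargetSet, first: int, last: int) -> str:
    covered: dict[str, int] = {}
    for j in range(first, last + 1):
        g = targets.genes[j]
        covered[g] = covered.get(g, 0) + 1
    full = [g for g, n in covered.items() if n == targets.n_targets_of_gene(g)]
    if len(full) >= 2:
        return "multi_gene"
    if len(full) == 1:
        return "whole_gene"
    return "intragenic"


def call_segments(
    l2m: Log2RatioMatrix, thresholds: Thresholds | None = None
) -> list[CnvCall]:
    """Threshold each sample's log2 ratios and merge contiguous runs.

    A target is aberrant when its log2 ratio is >= ``gain_min_log2``
    (gain) or <= ``loss_max_log2`` (loss), both inclusive.  Maximal
    runs of same-direction aberrant targets that are contiguous in
    genome order and lie on one chromosome form one call; masked
    targets break contiguity.  An empty list is a valid result.
    """
    thresholds = thresholds or Thresholds()
    targets = l2m.targets
    calls: list[CnvCall] = []
    n_targets = len(targets)
    for i, meta in enumerate(l2m.samples):
        row = l2m.log2ratio[i]
        masked = l2m.mask[i]
        status = np.zeros(n_targets, dtype=np.int8)
        ok = ~masked & np.isfinite(row)
        status[ok & (row >= thresholds.gain_min_log2)] = 1
        status[ok & (row <= thresholds.loss_max_log2)] = -1
        j = 0
        while j < n_targets:
            s = status[j]
            if s == 0:
                j += 1
                continue
            k = j
            while (
                k + 1 < n_targets
                and status[k + 1] == s
                and targets.chroms[k + 1] == targets.chroms[j]
            ):
                k += 1
            per_t = tuple(float(v) for v in row[j : k + 1])
            genes = tuple(dict.fromkeys(str(g) for g in targets.genes[j : k + 1]))
            calls.append(
                CnvCall(
                    sample_id=meta.sample_id,
                    chrom=str(targets.chroms[j]),
                    start=int(targets.starts[j]),
                    end=int(targets.ends[k]),
                    genes=genes,
                    first_target=j,
                    last_target=k,
                    direction="gain" if s > 0 else "loss",
                    mean_log2=float(np.mean(per_t)),
                    per_target_log2=per_t,
                    span_kind=_span_kind(targets, j, k),
                    exon_span=(
                        str(targets.labels[j])
                        if j == k
                        else f"{targets.labels[j]}..{targets.labels[k]}"
                    ),
                )
            )
            j = k + 1
    return calls


_CALL_COLUMNS = (
    "sample_id\tchrom\tstart\tend\tgenes\texon_span\tdirection\t"
    "n_targets\tmean_log2\tspan_kind\tfirst_target\tlast_target"
)


def write_calls_tsv(
    calls: Sequence[CnvCall],
    path: str | Path,
    extra_columns: dict[str, Sequence] | None = None,
) -> None:
    """Write calls as TSV; ``extra_columns`` append aligned annotation."""
    extra = extra_columns or {}
    for name, vals in extra.items():
        if len(vals) != len(calls):
            raise ValidationError(f"extra column {name!r} length mismatch")
    with open(path, "w", encoding="utf-8") as fh:
        header = _CALL_COLUMNS
        if extra:
            header += "\t" + "\t".join(extra)
        fh.write(header + "\n")
        for idx, c in enumerate(calls):
            rowvals = [
                c.sample_id,
                c.chrom,
                str(c.start),
                str(c.end),
                ",".join(c.genes),
                c.exon_span,
                c.direction,
                str(c.n_targets),
                f"{c.mean_log2:.6f}",
                c.span_kind,
                str(c.first_target),
                str(c.last_target),
            ]
            for vals in extra.values():
                rowvals.append(str(vals[idx]))
            fh.write("\t".join(rowvals) + "\n")


def write_calls_vcf(calls: Sequence[CnvCall], path: str | Path) -> None:
    """Write calls as minimal VCF 4.2 symbolic <DEL>/<DUP> records."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write(
            '##INFO=<ID=END,Number=1,Type=Integer,'
            'Description="End position of the variant">\n'
        )
        fh.write(
            '##INFO=<ID=FOLD_CHANGE,Number=1,Type=Float,'
            'Description="2^mean_log2 depth fold change">\n'
        )
        fh.write(
            '##INFO=<ID=SAMPLE,Number=1,Type=String,'
            'Description="Carrier sample">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            alt = "<DUP>" if c.direction == "gain" else "<DEL>"
            fold = 2.0 ** c.mean_log2
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t.\tN\t{alt}\t.\t.\t"
                f"END={c.end};FOLD_CHANGE={fold:.4f};SAMPLE={c.sample_id}\n"
            )
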