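"""Targets, samples, and coverage-matrix I/O.

File formats
------------
* Targets: BED 4+ (0-based half-open), name column ``GENE_exN``.
* Coverage: TSV with an ``interval`` key column (``chrom:start-end``,
  1-based inclusive, the convention of depth-of-coverage interval
  summaries) and one mean-depth column per sample.
* Sample metadata: TSV with columns sample_id, batch_id, sex,
  phenotype, panel.

All text I/O is UTF-8 and tab-delimited; lines starting with ``#`` are
ignored.  Internally every coordinate is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


class PanelCnvError(Exception):
    """Base class for all panelcnv errors."""


class ParseError(PanelCnvError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PanelCnvError):
    """Parsed content violates an invariant of the data model."""


class AlignmentError(PanelCnvError):
    """Rows or columns of a matrix do not match the expected keys."""


SEXES = ("female", "male", "unknown")
PHENOTYPES = ("HCM", "DCM", "ARVC", "LVNC", "RCM", "NOS", "other")
PANELS = ("PanCardio", "HCM", "DCM", "ARVC", "LVNC")

_SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Natural chromosome order: 1..22 < X < Y < MT < other (lexical)."""
    name = chrom[3:] if chrom.startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    if name in special:
        return (0, special[name], "")
    return (1, 0, name)


@dataclass(frozen=True)
class TargetInterval:
    """One captured exon-level interval.

    Coordinates are 0-based half-open; ``genome_order`` is the rank of
    the interval in (chrom, start) order over the whole target set and
    is the x-axis of per-sample log2 profiles.
    """

    chrom: str
    start: int
    end: int
    gene: str
    label: str
    genome_order: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    @property
    def is_sex_chrom(self) -> bool:
        return self.chrom in _SEX_CHROMS

    @property
    def key(self) -> str:
        """Row key in the 1-based inclusive dialect of coverage TSVs."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


class TargetSet:
    """An ordered, validated collection of :class:`TargetInterval`.

    Construction sorts intervals by (chrom, start) and assigns
    ``genome_order`` 0..n-1; duplicate intervals and overlapping
    intervals within one gene are rejected.
    """

    def __init__(self, intervals: Iterable[TargetInterval]) -> None:
        raw = sorted(
            intervals, key=lambda t: (_chrom_sort_key(t.chrom), t.start, t.end)
        )
        if not raw:
            raise ValidationError("empty target set")
        seen: set[tuple[str, int, int]] = set()
        rebuilt = []
        for order, t in enumerate(raw):
            coords = (t.chrom, t.start, t.end)
            if coords in seen:
                raise ValidationError(
                    f"duplicate interval {t.chrom}:{t.start}-{t.end}"
                )
            seen.add(coords)
            rebuilt.append(
                TargetInterval(t.chrom, t.start, t.end, t.gene, t.label, order)
            )
        # non-overlap within a gene on one chromosome
        last_end: dict[tuple[str, str], int] = {}
        for t in rebuilt:
            key = (t.gene, t.chrom)
            if key in last_end and t.start < last_end[key]:
                raise ValidationError(
                    f"overlapping intervals for gene {t.gene} on {t.chrom}"
                )
            last_end[key] = t.end
        self._intervals: tuple[TargetInterval, ...] = tuple(rebuilt)
        self.chroms = np.array([t.chrom for t in rebuilt])
        self.starts = np.array([t.start for t in rebuilt], dtype=np.int64)
        self.ends = np.array([t.end for t in rebuilt], dtype=np.int64)
        self.genes = np.array([t.gene for t in rebuilt])
        self.labels = np.array([t.label for t in rebuilt])
        self.is_sex_chrom = np.array([t.is_sex_chrom for t in rebuilt])
        self._targets_per_gene: dict[str, int] = {}
        for g in self.genes:
            self._targets_per_gene[g] = self._targets_per_gene.get(g, 0) + 1

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[TargetInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> TargetInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TargetSet):
            return NotImplemented
        return self._intervals == other._intervals

    def n_targets_of_gene(self, gene: str) -> int:
        return self._targets_per_gene[gene]

    @property
    def keys(self) -> list[str]:
        return [t.key for t in self._intervals]


_NAME_RE = re.compile(r"^(?P<gene>[^\s]+)_(?P<exon>ex\w+)$")


def read_targets(path: str | Path) -> TargetSet:
    """Read a 4+ column BED file into a :class:`TargetSet`.

    The BED name column must encode gene and exon as ``GENE_exN``.
    Input line order is irrelevant: intervals are sorted and
    ``genome_order`` assigned by (chrom, start).
    """
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=4 BED columns, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: start >= end ({start} >= {end})"
                )
            m = _NAME_RE.match(name)
            if m:
                gene = m.group("gene")
            else:
                # fall back: everything before the last underscore
                gene = name.rsplit("_", 1)[0] if "_" in name else name
            intervals.append(TargetInterval(chrom, start, end, gene, name, 0))
    if not intervals:
        raise ParseError(f"{path}: no intervals found")
    return TargetSet(intervals)


def write_targets(targets: TargetSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.label}\n")


@dataclass(frozen=True)
class SampleMeta:
    """Identity, batch membership, and phenotype of one sequenced sample."""

    sample_id: str
    batch_id: str
    sex: str = "unknown"
    phenotype: str = "other"
    panel: str = "PanCardio"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(
                f"sample {self.sample_id}: sex must be one of {SEXES}"
            )
        if self.phenotype not in PHENOTYPES:
            raise ValidationError(
                f"sample {self.sample_id}: phenotype must be one of {PHENOTYPES}"
            )
        if self.panel not in PANELS:
            raise ValidationError(
                f"sample {self.sample_id}: panel must be one of {PANELS}"
            )


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "batch_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                batch_id=row["batch_id"],
                sex=row.get("sex", "unknown") or "unknown",
                phenotype=row.get("phenotype", "other") or "other",
                panel=row.get("panel", "PanCardio") or "PanCardio",
            )
        )
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample_id")
    return metas


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tbatch_id\tsex\tphenotype\tpanel\n")
        for m in samples:
            fh.write(
                f"{m.sample_id}\t{m.batch_id}\t{m.sex}\t{m.phenotype}\t{m.panel}\n"
            )


class CoverageMatrix:
    """Samples x targets matrix of non-negative mean per-interval depth."""

    def __init__(
        self,
        targets: TargetSet,
        samples: Sequence[SampleMeta],
        depth: np.ndarray,
    ) -> None:
        depth = np.asarray(depth, dtype=float)
        if depth.shape != (len(samples), len(targets)):
            raise ValidationError(
                f"depth shape {depth.shape} does not match "
                f"{len(samples)} samples x {len(targets)} targets"
            )
        if not np.all(np.isfinite(depth)):
            raise ValidationError("depth matrix contains non-finite values")
        if np.any(depth < 0):
            raise ValidationError("depth matrix contains negative values")
        self.targets = targets
        self.samples = list(samples)
        self.depth = depth

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.samples]

    @property
    def batch_ids(self) -> list[str]:
        return sorted({m.batch_id for m in self.samples})

    def subset_batch(self, batch_id: str) -> "CoverageMatrix":
        idx = [i for i, m in enumerate(self.samples) if m.batch_id == batch_id]
        if not idx:
            raise ValidationError(f"no samples in batch {batch_id!r}")
        return CoverageMatrix(
            self.targets, [self.samples[i] for i in idx], self.depth[idx]
        )

    def sample_index(self, sample_id: str) -> int:
        for i, m in enumerate(self.samples):
            if m.sample_id == sample_id:
                return i
        raise KeyError(sample_id)


def read_coverage_matrix(
    path: str | Path, targets: TargetSet, meta: Sequence[SampleMeta]
) -> CoverageMatrix:
    """Read a per-interval mean-depth TSV aligned to ``targets``.

    Rows are keyed ``chrom:start-end`` (1-based inclusive); columns are
    samples.  Every sample column must appear in ``meta`` and the row
    keys must match the target set exactly (any order).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, float_precision="round_trip"
    )
    meta_by_id = {m.sample_id: m for m in meta}
    unknown_samples = [c for c in df.columns if c not in meta_by_id]
    if unknown_samples:
        raise AlignmentError(
            f"{path}: samples missing from metadata: {unknown_samples}"
        )
    expected = targets.keys
    extra = sorted(set(df.index.astype(str)) - set(expected))
    if extra:
        raise AlignmentError(
            f"{path}: rows not present in target set: {extra}"
        )
    missing_rows = sorted(set(expected) - set(df.index.astype(str)))
    if missing_rows:
        raise AlignmentError(
            f"{path}: rows missing for targets: {missing_rows}"
        )
    df = df.loc[expected]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: non-numeric depth values")
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ValidationError(f"{path}: negative or non-finite depth values")
    ordered_meta = [meta_by_id[c] for c in df.columns]
    return CoverageMatrix(targets, ordered_meta, values.T)


def write_coverage_matrix(matrix: CoverageMatrix, path: str | Path) -> None:
    """Write a coverage matrix in the TSV dialect read_coverage_matrix reads.

    Depths are written with ``repr``-fidelity so that a write/read round
    trip reproduces the exact float values.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("interval\t" + "\t".join(matrix.sample_ids) + "\n")
        for j, t in enumerate(matrix.targets):
            row = "\t".join(repr(float(v)) for v in matrix.depth[:, j])
            fh.write(f"{t.key}\t{row}\n")
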