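"""End-to-end orchestration: files in, reviewed/classified calls and a
cohort summary out."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import (
    Classification,
    GeneKnowledge,
    classify_cnv,
    load_gene_knowledge,
)
from .cohort import (
    ClassifiedRecord,
    CohortComposition,
    CohortSummary,
    FixtureCall,
    summarize_cohort,
)
from .core import (
    CnvCall,
    Log2RatioMatrix,
    Thresholds,
    call_segments,
    fractional_coverage,
    log2_ratios,
    write_calls_tsv,
    write_calls_vcf,
)
from .io import (
    ValidationError,
    read_coverage_matrix,
    read_sample_meta,
    read_targets,
)
from .plotting import plot_sample_profile
from .review import (
    DEFAULT_FREQ_CUTOFF,
    DEFAULT_NOISE_MULTIPLIER,
    ReviewScore,
    review_score,
)

logger = logging.getLogger(__name__)

_version = "0.1.0"


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    targets_path: Path
    coverage_path: Path
    samples_path: Path
    out_dir: Path
    kb_path: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    freq_cutoff: float = DEFAULT_FREQ_CUTOFF
    noise_multiplier: float = DEFAULT_NOISE_MULTIPLIER
    seed: int = 17
    write_vcf: bool = False
    make_plots: bool = True

    def validate(self) -> None:
        for name in ("targets_path", "coverage_path", "samples_path"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"{name.replace('_path', '')} file not found: {p}")
        if self.kb_path is not None and not Path(self.kb_path).exists():
            raise ValidationError(f"knowledge table not found: {self.kb_path}")

    def as_dict(self) -> dict:
        return {
            "targets": str(self.targets_path),
            "coverage": str(self.coverage_path),
            "samples": str(self.samples_path),
            "kb": str(self.kb_path) if self.kb_path else "packaged",
            "gain_min_log2": self.thresholds.gain_min_log2,
            "loss_max_log2": self.thresholds.loss_max_log2,
            "pseudocount": self.thresholds.pseudocount,
            "freq_cutoff": self.freq_cutoff,
            "noise_multiplier": self.noise_multiplier,
            "seed": self.seed,
        }


@dataclass
class PipelineResult:
    calls: list[CnvCall]
    reviews: list[ReviewScore]
    classifications: list[Classification]
    summary: CohortSummary
    out_dir: Path
    files: list[Path]


def _write_log2_tsv(l2m: Log2RatioMatrix, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "interval\t" + "\t".join(m.sample_id for m in l2m.samples) + "\n"
        )
        for j, t in enumerate(l2m.targets):
            cells = []
            for i in range(len(l2m.samples)):
                if l2m.mask[i, j] or not np.isfinite(l2m.log2ratio[i, j]):
                    cells.append("NA")
                else:
                    cells.append(f"{l2m.log2ratio[i, j]:.6f}")
            fh.write(t.key + "\t" + "\t".join(cells) + "\n")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Run normalization, calling, review, classification and summary.

    Writes per-batch log2 matrices, an annotated calls TSV (optionally
    VCF), a cohort summary TSV and text report, a provenance block, and
    one profile plot per sample with at least one call.  Partial
    outputs are removed if any stage fails.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def register(path: Path) -> Path:
        created.append(path)
        return path

    try:
        targets = read_targets(cfg.targets_path)
        meta = read_sample_meta(cfg.samples_path)
        matrix = read_coverage_matrix(cfg.coverage_path, targets, meta)
        kb = load_gene_knowledge(cfg.kb_path)
        # panel genes without curated records classify conservatively
        # (mechanism unknown -> losses are VUS, never P_LP)
        for gene in dict.fromkeys(str(g) for g in targets.genes):
            if gene not in kb:
                kb[gene] = GeneKnowledge(
                    gene=gene,
                    diseases=frozenset(),
                    mechanism="unknown",
                    inheritance="AD",
                )

        calls: list[CnvCall] = []
        l2m_by_sample: dict[str, Log2RatioMatrix] = {}
        for batch_id in matrix.batch_ids:
            sub = matrix.subset_batch(batch_id)
            l2m = log2_ratios(fractional_coverage(sub), cfg.thresholds)
            _write_log2_tsv(l2m, register(out / f"log2_{batch_id}.tsv"))
            for m in sub.samples:
                l2m_by_sample[m.sample_id] = l2m
            calls.extend(call_segments(l2m, cfg.thresholds))

        n_samples = len(matrix.samples)
        reviews = [
            review_score(
                c,
                l2m_by_sample[c.sample_id],
                calls,
                n_samples,
                freq_cutoff=cfg.freq_cutoff,
                noise_multiplier=cfg.noise_multiplier,
            )
            for c in calls
        ]
        classifications = [
            classify_cnv(c, kb, verdict=r.verdict)
            for c, r in zip(calls, reviews)
        ]

        write_calls_tsv(
            calls,
            register(out / "calls.tsv"),
            extra_columns={
                "cohort_freq": [f"{r.cohort_freq:.6f}" for r in reviews],
                "batch_noise": [f"{r.batch_noise:.6f}" for r in reviews],
                "signal": [f"{r.signal:.6f}" for r in reviews],
                "verdict": [r.verdict for r in reviews],
                "tier": [c.tier for c in classifications],
                "rationale": ["+".join(c.rationale) for c in classifications],
                "predicted_outcome": [
                    c.predicted_outcome for c in classifications
                ],
            },
        )
        if cfg.write_vcf:
            write_calls_vcf(calls, register(out / "calls.vcf"))

        meta_by_id = {m.sample_id: m for m in meta}
        phen_counts: dict[str, int] = {}
        for m in meta:
            phen_counts[m.phenotype] = phen_counts.get(m.phenotype, 0) + 1
        comp = CohortComposition(
            phenotype_counts=phen_counts, total=n_samples
        )
        records = [
            ClassifiedRecord(
                patient_id=c.sample_id,
                sex=meta_by_id[c.sample_id].sex,
                age="",
                phenotype=meta_by_id[c.sample_id].phenotype,
                panel=meta_by_id[c.sample_id].panel,
                call=FixtureCall(
                    genes=c.genes,
                    region=c.exon_span,
                    direction=c.direction,
                    span_kind=c.span_kind,
                ),
                classification=cls,
            )
            for c, r, cls in zip(calls, reviews, classifications)
            if r.verdict == "pass"
        ]
        summary = summarize_cohort(records, comp)
        summary.to_frame().to_csv(
            register(out / "summary.tsv"), sep="\t", index=False
        )
        register(out / "report.txt").write_text(
            summary.render_report(), encoding="utf-8"
        )

        if cfg.make_plots:
            plot_dir = out / "plots"
            plot_dir.mkdir(exist_ok=True)
            flagged = sorted({c.sample_id for c in calls})
            for sid in flagged:
                plot_sample_profile(
                    sid,
                    l2m_by_sample[sid],
                    calls,
                    register(plot_dir / f"{sid}.png"),
                    cfg.thresholds,
                )

        config_yaml = yaml.safe_dump(cfg.as_dict(), sort_keys=True)
        provenance = {
            "tool": "panelcnv",
            "version": _version,
            "seed": cfg.seed,
            "config_sha256": hashlib.sha256(
                config_yaml.encode()
            ).hexdigest(),
            "config": cfg.as_dict(),
            "n_samples": n_samples,
            "n_targets": len(targets),
            "n_calls": len(calls),
        }
        register(out / "provenance.yaml").write_text(
            yaml.safe_dump(provenance, sort_keys=True), encoding="utf-8"
        )
    except Exception:
        for p in created:
            try:
                p.unlink()
            except OSError:  # pragma: no cover
                pass
        raise
    return PipelineResult(
        calls=calls,
        reviews=reviews,
        classifications=classifications,
        summary=summary,
        out_dir=out,
        files=created,
    )
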