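"""Rule-based clinical classification of CNV calls.

A deliberately simplified three-tier scheme driven by per-gene
disease-mechanism knowledge: exonic deletions in genes whose pathogenic
spectrum is dominated by loss-of-function variants are tier P_LP;
duplications are uncertain (intragenic duplications most likely disrupt
the reading frame, hence predicted LOF, but tandem-vs-insertional
ambiguity keeps them VUS; whole-gene or multi-gene duplications have no
predictable outcome); high-cohort-frequency loci are benign.  The full
ACMG/AMP evidence framework (segregation, population databases,
functional data) is intentionally out of scope, and pathogenic vs
likely-pathogenic is not distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import pandas as pd

from .io import PanelCnvError, ValidationError

MECHANISMS = ("LOF", "GOF", "unknown")
INHERITANCE = ("AD", "XL", "AR")
TIERS = ("P_LP", "VUS", "B_LB")


@dataclass(frozen=True)
class GeneKnowledge:
    """Disease-mechanism record for one panel gene."""

    gene: str
    diseases: frozenset[str]
    mechanism: str
    inheritance: str
    n_tested: int | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValidationError(
                f"gene {self.gene}: mechanism must be one of {MECHANISMS}"
            )
        if self.inheritance not in INHERITANCE:
            raise ValidationError(
                f"gene {self.gene}: inheritance must be one of {INHERITANCE}"
            )


@dataclass(frozen=True)
class Classification:
    """Tier plus the ordered rule identifiers that produced it."""

    tier: str
    rationale: tuple[str, ...]
    predicted_outcome: str  # 'LOF' | 'unknown'


class _CallLike(Protocol):
    genes: tuple[str, ...]
    direction: str
    span_kind: str


def load_gene_knowledge(path: str | Path | None = None) -> dict[str, GeneKnowledge]:
    """Load the gene-knowledge table (packaged copy by default)."""
    if path is None:
        ref = resources.files("panelcnv.data") / "gene_knowledge.tsv"
        with resources.as_file(ref) as p:
            return load_gene_knowledge(p)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    kb: dict[str, GeneKnowledge] = {}
    for _, row in df.iterrows():
        gene = row["gene"]
        if gene in kb:
            raise ValidationError(f"gene {gene} appears more than once")
        kb[gene] = GeneKnowledge(
            gene=gene,
            diseases=frozenset(row["diseases"].split(",")),
            mechanism=row["mechanism"],
            inheritance=row["inheritance"],
            n_tested=int(row["n_tested"]) if "n_tested" in row else None,
        )
    return kb


def classify_cnv(
    call: _CallLike,
    kb: Mapping[str, GeneKnowledge],
    verdict: str = "pass",
) -> Classification:
    """Classify one reviewed call.

    Rules fire in order:

    R1  artifact-frequency verdict -> B_LB (a >=1% cohort frequency is
        incompatible with a highly penetrant dominant variant).
    R2  loss in a gene (all spanned genes) with LOF mechanism -> P_LP,
        predicted outcome LOF.
    R3  loss in a gene without established LOF mechanism -> VUS.
    R4  intragenic gain -> VUS, predicted outcome LOF (most intragenic
        duplications are tandem and frame-disrupting, but tandem vs
        insertional cannot be resolved from depth).
    R5  whole-gene or multi-gene gain -> VUS, predicted outcome unknown.
    """
    for gene in call.genes:
        if gene not in kb:
            raise PanelCnvError(f"gene {gene!r} absent from knowledge table")
    if verdict == "artifact_freq":
        return Classification("B_LB", ("R1",), "unknown")
    if call.direction == "loss":
        if all(kb[g].mechanism == "LOF" for g in call.genes):
            return Classification("P_LP", ("R2",), "LOF")
        return Classification("VUS", ("R3",), "LOF")
    if call.span_kind == "intragenic":
        return Classification("VUS", ("R4",), "LOF")
    return Classification("VUS", ("R5",), "unknown")


def classify_all(
    calls: Sequence[_CallLike],
    kb: Mapping[str, GeneKnowledge],
    verdicts: Sequence[str] | None = None,
) -> list[Classification]:
    verdicts = verdicts or ["pass"] * len(calls)
    return [classify_cnv(c, kb, v) for c, v in zip(calls, verdicts)]
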