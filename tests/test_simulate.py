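"""Synthetic-cohort generator: determinism, noiseless expectations,
event injection."""

import numpy as np
import pytest

from panelcnv.core import call_segments, fractional_coverage, log2_ratios
from panelcnv.io import ValidationError
from panelcnv.simulate import (
    ArtifactLocus,
    SimConfig,
    SimEvent,
    X_GENES,
    inject_event,
    simulate_cohort,
    synthetic_targets,
)


def _l2m(matrix):
    return log2_ratios(fractional_coverage(matrix))


def test_same_seed_bit_identical():
    cfg = SimConfig(n_batches=2, n_targets=60, seed=123,
                    artifact_loci=(ArtifactLocus(5, 6, 0.2),))
    m1, t1 = simulate_cohort(cfg)
    m2, t2 = simulate_cohort(cfg)
    assert np.array_equal(m1.depth, m2.depth)
    assert t1 == t2
    m3, _ = simulate_cohort(SimConfig(n_batches=2, n_targets=60, seed=124))
    assert not np.array_equal(m1.depth, m3.depth)


def test_synthetic_panel_structure():
    ts = synthetic_targets(200)
    assert len(ts) == 200
    x_genes = {t.gene for t in ts if t.chrom == "chrX"}
    assert x_genes == set(X_GENES)
    orders = [t.genome_order for t in ts]
    assert orders == sorted(orders) == list(range(200))


def test_noiseless_null_single_sex_is_exactly_zero():
    """With no noise, no events, and one sex stratum, every log2 ratio
    is 0 to floating-point precision."""
    cfg = SimConfig(noise_sd=0.0, sex_ratio=1.0, n_targets=50, seed=1)
    matrix, truth = simulate_cohort(cfg)
    assert truth == []
    l2m = _l2m(matrix)
    assert np.nanmax(np.abs(l2m.log2ratio)) < 1e-9


def test_noiseless_null_mixed_sex_is_near_zero():
    """Mixed batches couple sexes through the fractional denominator
    (males' halved X depth inflates their autosomal fractions), so the
    null sits within a small band rather than at exactly zero."""
    cfg = SimConfig(noise_sd=0.0, sex_ratio=0.5, n_targets=100, seed=2)
    matrix, _ = simulate_cohort(cfg)
    l2m = _l2m(matrix)
    assert np.nanmax(np.abs(l2m.log2ratio)) < 0.05
    assert not call_segments(l2m)


def test_noiseless_het_deletion_near_minus_one():
    """log2 of a noiseless heterozygous loss is -1, attenuated only by
    the carrier's slightly reduced total depth (small for exon-scale
    events on a large panel)."""
    ev = SimEvent(sample_index=0, first_target=10, last_target=12, copy_number=1)
    cfg = SimConfig(noise_sd=0.0, sex_ratio=1.0, n_targets=300, seed=3,
                    events=(ev,))
    matrix, _ = simulate_cohort(cfg)
    l2m = _l2m(matrix)
    assert np.allclose(l2m.log2ratio[0, 10:13], -1.0, atol=0.02)
    calls = call_segments(l2m)
    assert len(calls) == 1
    assert (calls[0].first_target, calls[0].last_target) == (10, 12)
    assert calls[0].direction == "loss"


def test_noiseless_trisomy_x_gain():
    """A female whole-X triplication under sex-aware normalization sits
    near +log2(1.5) on every X target (attenuated slightly by the
    carrier's inflated total depth) and is called as one multi-gene
    gain."""
    targets = synthetic_targets(100)
    x_idx = np.flatnonzero(targets.is_sex_chrom)
    ev = SimEvent(0, int(x_idx[0]), int(x_idx[-1]), copy_number=3,
                  kind="whole_chromosome")
    cfg = SimConfig(noise_sd=0.0, sex_ratio=1.0, n_targets=100, seed=4,
                    events=(ev,))
    matrix, _ = simulate_cohort(cfg, targets=targets)
    l2m = _l2m(matrix)
    assert np.allclose(l2m.log2ratio[0, x_idx], np.log2(1.5), atol=0.05)
    calls = call_segments(l2m)
    assert [
        (c.direction, c.span_kind) for c in calls if c.sample_id == matrix.samples[0].sample_id
    ] == [("gain", "multi_gene")]
    assert set(calls[0].genes) == set(X_GENES)
    assert not [c for c in calls if c.sample_id != matrix.samples[0].sample_id]


def test_event_span_validation():
    with pytest.raises(ValidationError):
        simulate_cohort(
            SimConfig(n_targets=20, events=(SimEvent(0, 15, 25, 1),), seed=5)
        )
    with pytest.raises(ValidationError):
        SimEvent(0, 5, 3, 1)


def test_inject_event_identity_and_scaling():
    cfg = SimConfig(noise_sd=0.0, sex_ratio=1.0, n_targets=300, seed=6)
    matrix, _ = simulate_cohort(cfg)
    same = inject_event(matrix, SimEvent(1, 5, 7, copy_number=2))
    assert np.array_equal(same.depth, matrix.depth)

    dup4 = inject_event(matrix, SimEvent(1, 5, 7, copy_number=4))
    l2m = _l2m(dup4)
    assert np.allclose(l2m.log2ratio[1, 5:8], 1.0, atol=0.05)

    hom = inject_event(matrix, SimEvent(1, 5, 6, copy_number=0))
    assert np.all(hom.depth[1, 5:7] == 0.0)
    l2m0 = _l2m(hom)
    deep = l2m0.log2ratio[1, 5:7]
    assert np.all(deep[np.isfinite(deep)] < -3.0)  # deep loss, per floor policy


def test_inject_event_rejects_overlap():
    cfg = SimConfig(noise_sd=0.0, n_targets=30, seed=7)
    matrix, _ = simulate_cohort(cfg)
    first = SimEvent(2, 4, 8, copy_number=1)
    matrix2 = inject_event(matrix, first)
    with pytest.raises(ValidationError, match="overlap"):
        inject_event(matrix2, SimEvent(2, 8, 10, copy_number=3), existing=[first])
    # disjoint span or another sample is fine
    inject_event(matrix2, SimEvent(2, 9, 10, copy_number=3), existing=[first])
    inject_event(matrix2, SimEvent(3, 4, 8, copy_number=3), existing=[first])


def test_artifact_loci_frequency_realized():
    cfg = SimConfig(n_batches=30, n_targets=50, seed=8,
                    artifact_loci=(ArtifactLocus(20, 21, 0.05, copy_number=3),))
    matrix, truth = simulate_cohort(cfg)
    carriers = [e for e in truth if e.source == "artifact"]
    # 300 samples at 5%: expect ~15 carriers
    assert 5 <= len(carriers) <= 30
    assert all(e.copy_number == 3 for e in carriers)
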