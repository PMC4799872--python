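"""Normalization and threshold calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panelcnv.core import (
    Thresholds,
    call_segments,
    fractional_coverage,
    log2_ratios,
)
from panelcnv.io import CoverageMatrix, SampleMeta, ValidationError

from conftest import (
    brute_force_calls,
    call_keys,
    make_l2m,
    make_samples,
    make_targets,
)


def _matrix(depth, targets=None, sexes=None, batch="B0"):
    depth = np.asarray(depth, dtype=float)
    if targets is None:
        targets = make_targets([("chr1", "G1", depth.shape[1])])
    if sexes is None:
        samples = make_samples(depth.shape[0], batch)
    else:
        samples = [
            SampleMeta(f"{batch}_S{i:02d}", batch, sex=s)
            for i, s in enumerate(sexes)
        ]
    return CoverageMatrix(targets, samples, depth)


# ---------------------------------------------------------------- fractional


def test_fractional_constant_matrix():
    fm = fractional_coverage(_matrix(np.full((10, 5), 100.0)))
    assert np.all(fm.frac == 0.2)


def test_fractional_simple_proportions():
    fm = fractional_coverage(_matrix([[50.0, 50.0, 100.0]]))
    assert np.allclose(fm.frac, [[0.25, 0.25, 0.5]], atol=0)


def test_fractional_zero_sample_named():
    depth = np.full((4, 3), 10.0)
    depth[2] = 0.0
    with pytest.raises(ValidationError, match="B0_S02"):
        fractional_coverage(_matrix(depth))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_fractional_rows_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    depth = rng.gamma(2.0, 50.0, size=(6, 12)) + 1e-3
    fm = fractional_coverage(_matrix(depth))
    assert np.allclose(fm.frac.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------- log2 ratios


def test_log2_exact_half_and_threehalves_of_median():
    """A sample at 0.5x the batch median is exactly -1; 1.5x is +log2(1.5).

    The carrier's depleted and amplified targets compensate, so its row
    total (the fractional denominator) is unchanged and the ratios are
    exact.
    """
    depth = np.full((5, 10), 100.0)
    depth[0, 0] = 50.0
    depth[0, 1] = 150.0
    l2m = log2_ratios(fractional_coverage(_matrix(depth)))
    assert l2m.log2ratio[0, 0] == pytest.approx(-1.0, abs=1e-12)
    assert l2m.log2ratio[0, 1] == pytest.approx(np.log2(1.5), abs=1e-12)
    assert abs(l2m.log2ratio[1, 0]) < 1e-12  # sample at the median


def test_log2_median_centering_even_batch():
    """Per-target stratum median of log2 ratios is 0 to 1e-9 even for
    even-sized batches."""
    rng = np.random.default_rng(42)
    depth = rng.lognormal(5.0, 0.4, size=(10, 30))
    l2m = log2_ratios(fractional_coverage(_matrix(depth)))
    med = np.median(l2m.log2ratio, axis=0)
    assert np.all(np.abs(med) < 1e-9)


def test_log2_scale_invariance():
    """Multiplying one sample's raw depths by c leaves its ratios unchanged."""
    rng = np.random.default_rng(7)
    depth = rng.lognormal(5.0, 0.3, size=(8, 20))
    base = log2_ratios(fractional_coverage(_matrix(depth)))
    for c in (0.01, 3.7, 250.0):
        scaled = depth.copy()
        scaled[3] *= c
        l2m = log2_ratios(fractional_coverage(_matrix(scaled)))
        assert np.allclose(l2m.log2ratio, base.log2ratio, atol=1e-9)


def test_log2_monotone_in_depth():
    """Raising one cell's depth never lowers that cell's log2 ratio."""
    rng = np.random.default_rng(3)
    depth = rng.lognormal(5.0, 0.3, size=(7, 15))
    for _ in range(50):
        i = rng.integers(0, 7)
        j = rng.integers(0, 15)
        before = log2_ratios(fractional_coverage(_matrix(depth)))
        bumped = depth.copy()
        bumped[i, j] *= 1.0 + rng.uniform(0.01, 2.0)
        after = log2_ratios(fractional_coverage(_matrix(bumped)))
        assert after.log2ratio[i, j] - before.log2ratio[i, j] > -1e-12


def test_log2_refuses_tiny_batch():
    with pytest.raises(ValidationError, match="at least"):
        log2_ratios(fractional_coverage(_matrix(np.full((2, 5), 10.0))))


def test_log2_sex_stratified_normalization():
    """X targets are normalized within sex: males at one copy sit at 0,
    and a small male stratum is masked rather than mis-normalized."""
    targets = make_targets([("chr1", "G1", 10), ("chrX", "GLA", 4)])
    sexes = ["female"] * 5 + ["male"] * 5
    depth = np.full((10, 14), 100.0)
    depth[5:, 10:] = 50.0  # male X at half depth
    l2m = log2_ratios(fractional_coverage(_matrix(depth, targets, sexes)))
    assert np.all(np.abs(l2m.log2ratio[:, 10:][~l2m.mask[:, 10:]]) < 0.05)
    assert not l2m.mask.any()

    sexes2 = ["female"] * 8 + ["male"] * 2
    depth2 = np.full((10, 14), 100.0)
    depth2[8:, 10:] = 50.0
    l2m2 = log2_ratios(fractional_coverage(_matrix(depth2, targets, sexes2)))
    assert l2m2.mask[8:, 10:].all()  # male stratum too small
    assert not l2m2.mask[:8].any()


def test_log2_masks_zero_median_target():
    depth = np.full((6, 8), 100.0)
    depth[:, 4] = 0.0  # capture dropout at one target
    l2m = log2_ratios(fractional_coverage(_matrix(depth)))
    assert l2m.masked_targets[4]
    assert not l2m.masked_targets[[0, 1, 2, 3, 5, 6, 7]].any()
    assert not call_segments(l2m)  # masked target produces no call


# ------------------------------------------------------------------- calling


def test_thresholds_are_inclusive():
    targets = make_targets([("chr1", "G1", 4)])
    vals = np.array([[0.40, 0.0, -0.55, 0.0]])
    calls = call_segments(make_l2m(targets, vals))
    assert call_keys(calls) == {("B0_S00", 0, 0, "gain"), ("B0_S00", 2, 2, "loss")}
    just_inside = np.array([[0.399999, 0.0, -0.549999, 0.39, -0.5]])
    targets5 = make_targets([("chr1", "G1", 5)])
    assert call_segments(make_l2m(targets5, just_inside)) == []


def test_thresholds_validation():
    with pytest.raises(ValidationError):
        Thresholds(gain_min_log2=-0.1)
    with pytest.raises(ValidationError):
        Thresholds(pseudocount=0.0)


def test_intragenic_loss_call_boundaries():
    """A -1 run over exons 12-20 of a 25-exon gene yields one intragenic
    loss of nine targets."""
    targets = make_targets([("chr11", "MYBPC3", 25)])
    vals = np.zeros((1, 25))
    vals[0, 11:20] = -1.0
    calls = call_segments(make_l2m(targets, vals))
    assert len(calls) == 1
    c = calls[0]
    assert (c.first_target, c.last_target) == (11, 19)
    assert c.n_targets == 9
    assert c.direction == "loss"
    assert c.span_kind == "intragenic"
    assert c.genes == ("MYBPC3",)
    assert c.mean_log2 == pytest.approx(-1.0)


def test_whole_gene_and_multi_gene_span_kinds():
    targets = make_targets([("chr12", "PKP2", 3), ("chr12", "OTHER", 3)])
    vals = np.zeros((1, 6))
    vals[0, :3] = 0.585
    calls = call_segments(make_l2m(targets, vals))
    assert [c.span_kind for c in calls] == ["whole_gene"]
    vals[0, :] = 0.585
    calls = call_segments(make_l2m(targets, vals))
    assert [c.span_kind for c in calls] == ["multi_gene"]


def test_calls_do_not_cross_chromosomes_and_masks_break_runs():
    targets = make_targets([("chr1", "G1", 3), ("chr2", "G2", 3)])
    vals = np.full((1, 6), -1.0)
    calls = call_segments(make_l2m(targets, vals))
    assert call_keys(calls) == {("B0_S00", 0, 2, "loss"), ("B0_S00", 3, 5, "loss")}
    mask = np.zeros((1, 6), dtype=bool)
    mask[0, 1] = True
    calls = call_segments(make_l2m(targets, vals, mask))
    assert call_keys(calls) == {
        ("B0_S00", 0, 0, "loss"),
        ("B0_S00", 2, 2, "loss"),
        ("B0_S00", 3, 5, "loss"),
    }


def test_call_segments_matches_brute_force_oracle():
    """200 random 8x40 log2 matrices: production segmentation equals an
    exhaustive per-target scan with naive run merging."""
    targets = make_targets(
        [("chr1", "G1", 10), ("chr1", "G2", 10), ("chr2", "G3", 20)]
    )
    th = Thresholds()
    rng = np.random.default_rng(17)
    for _ in range(200):
        vals = rng.normal(0.0, 0.45, size=(8, 40))
        mask = rng.random((8, 40)) < 0.05
        l2m = make_l2m(targets, vals, mask)
        assert call_keys(call_segments(l2m, th)) == brute_force_calls(l2m, th)
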