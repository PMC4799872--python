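"""Cohort-frequency filtering and the review-score surrogate."""

import numpy as np
import pytest

from panelcnv.benchmark import artifact_filter_experiment
from panelcnv.review import frequency_filter, review_score, same_locus

from conftest import make_call, make_l2m, make_targets


def _cohort(n_carriers, first=5, last=8, direction="loss"):
    return [
        make_call(f"S{i}", first, last, direction) for i in range(n_carriers)
    ]


def test_frequency_cutoff_boundary():
    """15/1425 carriers (1.05%) is an artifact locus; 14/1425 (0.98%) passes."""
    flagged = frequency_filter(_cohort(15), n_samples=1425)
    assert all(art for _, _, art in flagged)
    assert flagged[0][1] == pytest.approx(15 / 1425)
    passed = frequency_filter(_cohort(14), n_samples=1425)
    assert not any(art for _, _, art in passed)


def test_private_call_passes_small_cohort():
    res = frequency_filter([make_call("S0", 2, 4)], n_samples=10)
    assert res == [(res[0][0], 0.1, False)]


def test_reciprocal_overlap_locus_matching():
    a = make_call("S0", 0, 9, "loss")
    assert same_locus(a, make_call("S1", 5, 14, "loss"))  # 5/10 both ways
    assert not same_locus(a, make_call("S1", 6, 15, "loss"))  # 4/10
    assert not same_locus(a, make_call("S1", 0, 9, "gain"))
    # reciprocity: a small call inside a big one is not the same locus
    assert not same_locus(make_call("S0", 0, 0), make_call("S1", 0, 9))


def test_frequency_filter_idempotent_and_order_invariant():
    calls = _cohort(20) + [make_call("P0", 30, 31, "gain")]
    res = frequency_filter(calls, n_samples=500)
    verdict = {id(c): a for c, _, a in res}
    rev = frequency_filter(list(reversed(calls)), n_samples=500)
    assert {id(c): a for c, _, a in rev} == verdict
    # filtering the passing subset again flags nothing new
    survivors = [c for c, _, a in res if not a]
    again = frequency_filter(survivors, n_samples=500)
    assert not any(a for _, _, a in again)


def test_raising_cutoff_never_flags_more():
    calls = _cohort(8) + _cohort(3, first=20, last=22) + [make_call("P", 40, 40)]
    flagged_prev = None
    for cutoff in (0.001, 0.005, 0.01, 0.02, 0.1, 1.0):
        flagged = {
            i for i, (_, _, a) in enumerate(frequency_filter(calls, 500, cutoff)) if a
        }
        if flagged_prev is not None:
            assert flagged <= flagged_prev
        flagged_prev = flagged


def test_review_score_rule_arithmetic():
    """signal 0.45 against a non-carrier MAD of 0.30 is low_quality
    (0.45 < 2 x 0.30); a clean 1.0-signal call passes."""
    targets = make_targets([("chr1", "G1", 10)])
    vals = np.zeros((6, 10))
    # noisy background at targets 2-3 with MAD 0.30 across non-carriers
    vals[1:, 2] = [0.3, -0.3, 0.3, -0.3, 0.45]
    vals[1:, 3] = [-0.3, 0.3, -0.3, 0.3, -0.45]
    vals[0, 2:4] = -0.45
    l2m = make_l2m(targets, vals)
    noisy = make_call("B0_S00", 2, 3, "loss", mean_log2=-0.45)
    score = review_score(noisy, l2m, [noisy], n_samples=600)
    assert score.batch_noise == pytest.approx(0.30)
    assert score.signal == pytest.approx(0.45)
    assert score.verdict == "low_quality"

    clean_vals = np.zeros((6, 10))
    clean_vals[0, 5:7] = -1.0
    clean = make_call("B0_S00", 5, 6, "loss", mean_log2=-1.0)
    score = review_score(clean, make_l2m(targets, clean_vals), [clean], 600)
    assert score.verdict == "pass"
    assert score.cohort_freq == pytest.approx(1 / 600)


def test_review_score_artifact_precedence():
    """A call overlapping a 2%-frequency locus is artifact_freq even if
    it would also be low quality."""
    targets = make_targets([("chr1", "G1", 10)])
    l2m = make_l2m(targets, np.zeros((6, 10)))
    cohort = [make_call(f"C{i}", 4, 5, "loss") for i in range(10)]
    mine = make_call("B0_S00", 4, 5, "loss", mean_log2=-0.6)
    score = review_score(mine, l2m, cohort + [mine], n_samples=500)
    assert score.cohort_freq >= 0.02
    assert score.verdict == "artifact_freq"


def test_review_score_unknown_reference_errors():
    targets = make_targets([("chr1", "G1", 4)])
    l2m = make_l2m(targets, np.zeros((4, 4)))
    stray = make_call("NOT_IN_BATCH", 0, 1)
    with pytest.raises(Exception, match="NOT_IN_BATCH"):
        review_score(stray, l2m, [stray], 10)
    beyond = make_call("B0_S00", 2, 9)
    with pytest.raises(Exception, match="not in"):
        review_score(beyond, l2m, [beyond], 10)


def test_planted_artifacts_removed_true_events_kept():
    """On a 500-sample cohort with recurrent (>=2%) artifact loci and
    private spike-ins, the 1% filter removes every artifact-locus call
    and no true-event call."""
    res = artifact_filter_experiment(seed=17)
    assert res.n_artifact_calls > 20
    assert res.n_true_calls >= 30
    assert res.artifact_removal_rate == 1.0
    assert res.true_loss_rate == 0.0
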