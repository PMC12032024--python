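"""REM-period segmentation and the REM metric panel against brute force."""

import itertools

import numpy as np
import pytest

from remsleep import (
    Hypnogram,
    night_metrics,
    rd1,
    rem_efficiency,
    rem_latency,
    rem_percent,
    rem_time,
    segment_rem_periods,
    total_night_rd,
)
from remsleep.errors import UndefinedMetric

from conftest import hyp
import oracles


def test_no_rem_gives_empty_segmentation():
    assert segment_rem_periods(hyp(["S2"] * 40)) == []


def test_short_gap_merges_into_one_period():
    h = hyp(["S2"] * 20 + ["REM"] * 6 + ["S2"] * 10 + ["REM"] * 8 + ["S2"] * 40)
    (p,) = segment_rem_periods(h)
    assert (p.start, p.end) == (20, 44)
    assert p.rem_minutes == 7.0  # 5-min gap < 15 min merges
    assert p.completed


def test_fifteen_minute_gap_separates_periods():
    h = hyp(["REM"] * 6 + ["S2"] * 30 + ["REM"] * 6)
    ps = segment_rem_periods(h)
    assert len(ps) == 2


def test_sub_three_minute_candidate_discarded():
    h = hyp(["S2"] * 10 + ["REM"] * 4 + ["S2"] * 40)
    assert segment_rem_periods(h) == []


def test_truncated_final_period_not_completed():
    h = hyp(["S2"] * 10 + ["REM"] * 8 + ["S2"] * 4)
    (p,) = segment_rem_periods(h)
    assert not p.completed


def test_exhaustive_segmentation_matches_brute_force():
    for n in range(1, 11):
        for tokens in itertools.product(("S2", "REM"), repeat=n):
            got = segment_rem_periods(Hypnogram(stages=tokens))
            want = oracles.naive_segment(list(tokens))
            assert [(p.start, p.end, p.rem_minutes, p.completed) for p in got] == want


def test_segmentation_idempotent_on_period_epochs():
    h = hyp(["S2"] * 12 + ["REM"] * 6 + ["S2"] * 4 + ["REM"] * 6 + ["S2"] * 40)
    ps = segment_rem_periods(h)
    (p,) = ps
    sub = Hypnogram(stages=h.stages[p.start:p.end])
    (q,) = segment_rem_periods(sub)
    assert (q.rem_minutes, q.end - q.start) == (p.rem_minutes, p.end - p.start)


@pytest.mark.parametrize(
    "tokens, expected",
    [
        (["S2"] * 140 + ["REM"] * 8 + ["S2"] * 30, 70.0),
        (["S2"] * 4 + ["REM"] * 8 + ["S2"] * 30, 2.0),
        (["S2"] * 40, None),
    ],
)
def test_rem_latency_from_onset_to_first_period(tokens, expected):
    h = hyp(tokens)
    assert rem_latency(h, segment_rem_periods(h)) == expected


def test_rem_latency_immediately_after_onset():
    h = hyp(["S2"] + ["REM"] * 8 + ["S2"] * 30)
    assert rem_latency(h, segment_rem_periods(h)) == 0.5


def test_rem_latency_is_elapsed_time_including_wake():
    h = hyp(["S2"] + ["W"] * 4 + ["REM"] * 8 + ["S2"] * 30)
    assert rem_latency(h, segment_rem_periods(h)) == 2.5


def test_rem_time_counts_all_rem_epochs():
    h = hyp(["S2"] * 10 + ["REM"] * 180 + ["S2"] * 10)
    assert rem_time(h) == 90.0
    assert rem_percent(h) == pytest.approx(90.0)
    h2 = hyp(["S2"] * 10)
    assert rem_time(h2) == 0.0
    with pytest.raises(UndefinedMetric):
        rem_percent(hyp(["W", "S2"][:1] + ["W"]))  # no S2 -> undefined


def test_rem_efficiency_over_completed_periods():
    h = hyp(
        ["S2"] * 10 + ["REM"] * 20 + ["S2"] * 2 + ["REM"] * 12 + ["S2"] * 40
    )
    (p,) = segment_rem_periods(h)
    assert p.completed
    assert rem_efficiency([p]) == pytest.approx(100.0 * 16.0 / 17.0, abs=0.05)
    assert rem_efficiency([]) is None


def test_uninterrupted_period_efficiency_is_100():
    h = hyp(["S2"] * 10 + ["REM"] * 10 + ["S2"] * 40)
    assert rem_efficiency(segment_rem_periods(h)) == pytest.approx(100.0)


def test_total_night_rd_and_rd1_ratios():
    stages = ["S2"] * 10 + ["REM"] * 28 + ["S2"] * 40 + ["REM"] * 152 + ["S2"] * 40
    h = hyp(stages)
    counts = np.zeros(len(stages), dtype=int)
    rem_idx = [i for i, s in enumerate(stages) if s == "REM"]
    for k, i in enumerate(rem_idx):
        counts[i] = 1 if k % 3 == 0 else 0
    ps = segment_rem_periods(h)
    assert len(ps) == 2
    # first period: 28 epochs = 14 REM minutes
    first_count = counts[10:38].sum()
    assert rd1(counts, ps, h) == pytest.approx(first_count / 14.0)
    assert total_night_rd(counts, h) == pytest.approx(counts.sum() / 90.0)


def test_total_rd_invariant_to_permuting_rem_counts(rng):
    stages = ["S2"] * 10 + ["REM"] * 40 + ["S2"] * 40
    h = hyp(stages)
    counts = np.zeros(len(stages), dtype=int)
    counts[10:50] = rng.poisson(1.0, size=40)
    before = total_night_rd(counts, h)
    perm = counts.copy()
    perm[10:50] = rng.permutation(perm[10:50])
    assert total_night_rd(perm, h) == pytest.approx(before)


def test_period_rem_minutes_never_exceed_rem_time(rng):
    # nights begin at sleep onset so every REM epoch lies in the TST window
    for _ in range(30):
        stages = ("S2",) + tuple(
            rng.choice(["S2", "REM", "W"], size=300, p=[0.5, 0.3, 0.2])
        )
        h = Hypnogram(stages=stages)
        ps = segment_rem_periods(h)
        if not ps or oracles.naive_onset(stages) is None:
            continue
        assert sum(p.rem_minutes for p in ps) <= rem_time(h) + 1e-12


def test_night_metrics_composition_and_missing_markers():
    stages = ["W", "S1"] + ["S2"] * 40 + ["REM"] * 20 + ["S2"] * 40 + ["W"] * 4
    h = hyp(stages)
    counts = np.zeros(len(stages), dtype=int)
    counts[42:62] = 2
    nm = night_metrics(h, counts)
    ps = segment_rem_periods(h)
    assert nm.rl_minutes == rem_latency(h, ps)
    assert nm.rd1 == rd1(counts, ps, h)
    assert nm.total_night_rd == total_night_rd(counts, h)
    assert nm.rem_efficiency == rem_efficiency(ps)

    rem_free = night_metrics(hyp(["S2"] * 40), np.zeros(40, dtype=int))
    assert rem_free.rd1 is None
    assert rem_free.rl_minutes is None
    assert rem_free.total_night_rd is None
    assert rem_free.tst == 20.0
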