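"""Generator self-consistency: the pipeline recovers what was simulated."""

import numpy as np
import pandas as pd
import pytest

from remsleep import (
    CohortSpec,
    count_events_by_epoch,
    detect_eye_movements,
    night_metrics,
    rem_time,
    segment_rem_periods,
    simulate_clinical,
    simulate_cohort,
    simulate_em_events,
    simulate_eog,
    simulate_hypnogram,
    sleep_onset,
)
from remsleep.simulate import draw_subject_rate


def test_same_seed_reproduces_cohort_exactly():
    a = simulate_cohort(CohortSpec(n_trd=6, n_hv=4, n_responders=2,
                                   n_missing_response=0, seed=3))
    b = simulate_cohort(CohortSpec(n_trd=6, n_hv=4, n_responders=2,
                                   n_missing_response=0, seed=3))
    pd.testing.assert_frame_equal(a, b)


def test_night_length_matches_in_bed_span(rng):
    spec = CohortSpec(seed=1)
    h = simulate_hypnogram(spec, "TRD", "baseline", rng)
    assert len(h) == int(spec.in_bed_minutes * 2)
    assert h.lights_out is not None and h.lights_on is not None


def test_zero_rem_configuration_yields_rem_free_night(rng):
    spec = CohortSpec(rem_episode_means=(0.0,), rem_episode_min=0.0,
                      rem_episode_sd=0.0, seed=1)
    h = simulate_hypnogram(spec, "HV", "baseline", rng)
    assert "REM" not in h.stages
    nm = night_metrics(h, np.zeros(len(h), dtype=int))
    assert nm.rd1 is None and nm.rl_minutes is None
    assert nm.tst is not None


def test_rem_periods_recovered_distinct(rng):
    spec = CohortSpec(seed=2)
    h = simulate_hypnogram(spec, "TRD", "baseline", rng)
    ps = segment_rem_periods(h)
    assert 3 <= len(ps) <= 5
    assert all(p.rem_minutes >= 3.0 for p in ps)


def test_mean_segmented_latency_matches_latency_model(rng):
    spec = CohortSpec(seed=4)
    rls = []
    for _ in range(200):
        h = simulate_hypnogram(spec, "HV", "baseline", rng)
        ps = segment_rem_periods(h)
        rls.append(0.5 * (ps[0].start - sleep_onset(h)))
    rls = np.asarray(rls)
    expected = spec.latency_hv.expected()
    sem = rls.std(ddof=1) / np.sqrt(rls.size)
    assert abs(rls.mean() - expected) < 3.0 * sem


def test_zero_rate_gives_no_events(rng):
    spec = CohortSpec(seed=5)
    h = simulate_hypnogram(spec, "TRD", "baseline", rng)
    assert simulate_em_events(h, spec, "TRD", "baseline", rng, base_rate=0.0) == []


def test_poisson_event_count_moments(rng):
    """Events over a 14-REM-minute first period at 1.6/min average 22.4."""
    spec = CohortSpec(
        rem_episode_means=(14.0,), nrem_gap_mean=60.0, seed=6,
        rd1_multiplier_trd=1.0,
    )
    h = simulate_hypnogram(spec, "TRD", "baseline", rng)
    (p,) = [q for q in segment_rem_periods(h)[:1]]
    counts = []
    for _ in range(400):
        ev = simulate_em_events(h, spec, "TRD", "baseline", rng, base_rate=1.6)
        c = count_events_by_epoch(ev, h, deduplicate=False)
        counts.append(c[p.start:p.end].sum())
    counts = np.asarray(counts, dtype=float)
    expect = 1.6 * p.rem_minutes
    sem = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - expect) < 3.0 * sem


def test_first_period_multiplier_preserves_night_average(rng):
    spec = CohortSpec(seed=7)
    h = simulate_hypnogram(spec, "TRD", "baseline", rng)
    totals = []
    for _ in range(300):
        ev = simulate_em_events(h, spec, "TRD", "baseline", rng, base_rate=1.2)
        totals.append(len(ev))
    mean_rate = np.mean(totals) / rem_time(h)
    sem = np.std(totals, ddof=1) / np.sqrt(len(totals)) / rem_time(h)
    assert abs(mean_rate - 1.2) < 3.0 * sem


def test_eog_rendering_flat_and_subthreshold(rng):
    loc, roc = simulate_eog([], 30.0, noise_sd_uv=0.0, rng=rng)
    assert np.allclose(loc.samples, 0.0) and np.allclose(roc.samples, 0.0)
    spec = CohortSpec(seed=8)
    h = simulate_hypnogram(spec, "TRD", "baseline", rng)
    ev = simulate_em_events(h, spec, "TRD", "baseline", rng, base_rate=1.0)[:40]
    amps = np.full(len(ev), 10.0)  # far below the 25 uV criterion
    loc, _ = simulate_eog(ev, 600.0, noise_sd_uv=3.0, rng=rng, amplitudes_uv=amps)
    assert len(detect_eye_movements(loc)) <= 1


def test_clinical_scores_truncated_and_consistent(rng):
    spec = CohortSpec(seed=9)
    rd1 = rng.gamma(3.0, 0.5, size=63)
    clin = simulate_clinical(spec, rd1, rng)
    assert (clin.hamd_baseline >= spec.hamd_min).all()
    labeled = clin[clin.responder.notna()]
    assert len(labeled) == 63 - spec.n_missing_response
    # labels always consistent with the inclusive 50%-reduction rule
    frac = (labeled.hamd_baseline - labeled.hamd_day1) / labeled.hamd_baseline
    assert ((frac >= 0.5) == labeled.responder.astype(bool)).all()


def test_responder_count_calibrated_to_target(rng):
    spec = CohortSpec(seed=10)
    counts = []
    for _ in range(60):
        rd1 = rng.gamma(3.0, 0.5, size=63)
        clin = simulate_clinical(spec, rd1, rng)
        counts.append(clin.responder.dropna().astype(bool).sum())
    counts = np.asarray(counts, dtype=float)
    sem = counts.std(ddof=1) / np.sqrt(counts.size)
    assert abs(counts.mean() - spec.n_responders) < 3.0 * sem + 0.5


def test_zero_link_slope_decouples_response_from_rd1(rng):
    spec = CohortSpec(response_link_slope=0.0, seed=11)
    rd1 = np.linspace(0.1, 4.0, 61)
    spec.n_missing_response = 0
    resp = np.zeros(61)
    for _ in range(200):
        clin = simulate_clinical(spec, rd1, rng)
        resp += clin.responder.astype(bool).to_numpy()
    rate = resp / 200.0
    # response probability flat in RD1: low and high halves agree
    assert abs(rate[:30].mean() - rate[31:].mean()) < 0.05


def test_subject_rate_distribution_mean(rng):
    spec = CohortSpec(seed=12)
    lam = np.array([draw_subject_rate(spec, "TRD", rng) for _ in range(4000)])
    assert lam.mean() == pytest.approx(spec.em_base_rate_trd, rel=0.05)
    assert (lam > 0).all()
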