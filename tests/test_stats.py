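"""Non-parametric tests, Holm correction and summary tables against
enumeration oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from remsleep import (
    compare_groups,
    compare_paired,
    holm_adjust,
    mann_whitney,
    normality_gate,
    summary_table,
    wilcoxon_signed_rank,
)
from remsleep.errors import DegenerateSample

import oracles


def test_mwu_separated_triplets_exact():
    r = mann_whitney([1, 2, 3], [4, 5, 6])
    assert r.statistic == 0.0
    assert r.p == pytest.approx(0.1)
    assert r.method == "exact"
    assert r.effect_direction < 0


def test_mwu_identical_groups_p_one():
    r = mann_whitney([1, 2, 3], [1, 2, 3])
    assert r.p == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(6))
def test_mwu_exact_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    m, n = rng.integers(3, 5, size=2)
    pooled = rng.permutation(np.arange(1.0, m + n + 1))  # distinct -> no ties
    x, y = pooled[:m], pooled[m:]
    r = mann_whitney(x, y)
    assert r.method == "exact"
    assert r.p == pytest.approx(oracles.exact_mwu_p(list(x), list(y)), abs=1e-12)


def test_wilcoxon_all_positive_differences_exact():
    r = wilcoxon_signed_rank([2, 4, 6, 8, 10], [1, 2, 3, 4, 5])
    assert r.p == pytest.approx(0.0625)
    assert r.method == "exact"
    assert r.effect_direction > 0


def test_wilcoxon_all_zero_differences_is_null_result():
    r = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.p == 1.0
    assert r.z == 0.0


@pytest.mark.parametrize("seed", range(6))
def test_wilcoxon_exact_matches_sign_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(5, 11))
    mags = rng.permutation(np.arange(1.0, n + 1))
    signs = rng.choice([-1.0, 1.0], size=n)
    d = mags * signs
    r = wilcoxon_signed_rank(d, np.zeros(n))
    assert r.method == "exact"
    assert r.p == pytest.approx(oracles.exact_wilcoxon_p(list(d)), abs=1e-12)


def test_holm_family_matching_reported_pattern():
    """On the family {0.01, 0.002, 0.1} at alpha 0.05 Holm rejects exactly
    the first two hypotheses."""
    p_adj, reject = holm_adjust([0.01, 0.002, 0.1])
    assert reject.tolist() == [True, True, False]
    assert p_adj[0] == pytest.approx(0.02)
    assert p_adj[1] == pytest.approx(0.006)


def test_holm_single_p_unchanged():
    p_adj, _ = holm_adjust([0.03])
    assert p_adj[0] == pytest.approx(0.03)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
def test_holm_matches_stepdown_and_dominates_bonferroni(ps):
    p_adj, reject = holm_adjust(ps)
    want_adj, want_rej = oracles.stepdown_holm(ps)
    assert np.allclose(p_adj, want_adj)
    assert reject.tolist() == want_rej
    # Holm rejects everything Bonferroni rejects
    bonf = [min(1.0, p * len(ps)) <= 0.05 for p in ps]
    assert all(h or not b for h, b in zip(reject, bonf))
    # adjusted p-values non-decreasing in raw-p rank order
    order = np.argsort(ps)
    assert np.all(np.diff(np.asarray(p_adj)[order]) >= -1e-12)


def test_holm_rejects_invalid_family():
    with pytest.raises(ValueError):
        holm_adjust([])
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.5])


def test_normality_gate_degenerate_and_small_samples():
    with pytest.raises(DegenerateSample):
        normality_gate([1.0, 1.0, 1.0])
    with pytest.raises(DegenerateSample):
        normality_gate([1.0, 2.0])


def test_normality_gate_flags_heavy_tails(rng):
    x = rng.standard_cauchy(50)
    assert normality_gate(x).p < 0.05
    y = rng.normal(size=200)
    assert normality_gate(y).W > 0.97


def _toy_cohort():
    rows = []
    for i, v in enumerate([1.0, 2.0, 3.0]):
        rows.append({"subject_id": f"t{i}", "group": "TRD", "night": "baseline", "m": v})
        rows.append(
            {"subject_id": f"t{i}", "group": "TRD", "night": "post_treatment", "m": v - 1.0}
        )
    for i, v in enumerate([4.0, 5.0, 6.0]):
        rows.append({"subject_id": f"h{i}", "group": "HV", "night": "baseline", "m": v})
    return pd.DataFrame(rows)


def test_compare_groups_and_paired_on_cohort_frame():
    cohort = _toy_cohort()
    g = compare_groups(cohort, "m")
    assert g.p == pytest.approx(0.1)
    p = compare_paired(cohort, "m")
    assert p.n == (3,)
    assert p.effect_direction > 0  # baseline larger than post
    with pytest.raises(DegenerateSample):
        compare_paired(cohort[cohort.night == "baseline"], "m")


def test_summary_table_mean_sem_cells():
    cohort = _toy_cohort()
    tab = summary_table(cohort, ["m"], ("group", "night"))
    cell = tab[(tab.group == "TRD") & (tab.night == "baseline")].iloc[0]
    assert cell["mean"] == pytest.approx(2.0)
    assert cell["sem"] == pytest.approx(0.5773502692, abs=1e-6)
    single = summary_table(cohort.head(1), ["m"])
    assert np.isnan(single.iloc[0]["sem"])


def test_mwu_empty_group_signals():
    with pytest.raises(DegenerateSample):
        mann_whitney([], [1.0])
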