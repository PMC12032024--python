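"""Independent naive reference implementations used as test oracles.

Everything here recomputes quantities by a different algorithmic route
than the package (plain loops, exhaustive enumeration, rank identities)
and must stay independent of the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

SLEEP = {"S1", "S2", "S3", "S4", "REM"}


# --- sleep-architecture recounts -------------------------------------

def naive_onset(stages):
    idx = [i for i, s in enumerate(stages) if s == "S2"]
    return idx[0] if idx else None


def naive_final_waking(stages):
    idx = [i for i, s in enumerate(stages) if s in SLEEP]
    return idx[-1] + 1 if idx else None


def naive_window_count(stages, wanted):
    on, fw = naive_onset(stages), naive_final_waking(stages)
    if on is None:
        return None
    return 0.5 * sum(1 for s in stages[on:fw] if s in wanted)


def naive_se(stages):
    return 100.0 * sum(1 for s in stages if s in SLEEP) / len(stages)


# --- REM-period segmentation by iterative merging ---------------------

def naive_segment(stages, gap_counts_wake=True):
    """Maximal REM runs, merged pairwise while the qualifying gap is under
    15 minutes, then filtered by the 3-minute cumulative-REM minimum.
    Returns (start, end, rem_minutes, completed) tuples."""

    def qualifies(s):
        return s in ("S1", "S2", "S3", "S4") or (s == "W" and gap_counts_wake)

    runs = []
    i = 0
    while i < len(stages):
        if stages[i] == "REM":
            j = i
            while j < len(stages) and stages[j] == "REM":
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    if not runs:
        return []
    merged = [runs[0]]
    for start, end in runs[1:]:
        gap = sum(1 for k in range(merged[-1][1], start) if qualifies(stages[k]))
        if gap < 30:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    fw = naive_final_waking(stages)
    out = []
    for start, end in merged:
        rem_min = 0.5 * sum(1 for k in range(start, end) if stages[k] == "REM")
        if rem_min < 3.0:
            continue
        tail = 0
        completed = False
        for k in range(end, fw):
            if stages[k] == "REM":
                break
            if qualifies(stages[k]):
                tail += 1
            if tail >= 30:
                completed = True
                break
        out.append((start, end, rem_min, completed))
    return out


# --- naive REM metric recounts ---------------------------------------

def naive_rem_time(stages):
    return naive_window_count(stages, {"REM"})


def naive_bin_events(event_times, n_epochs):
    counts = [0] * n_epochs
    for t in event_times:
        e = int(t // 30)
        if 0 <= e < n_epochs:
            counts[e] += 1
    return counts


def naive_total_rd(stages, counts):
    on, fw = naive_onset(stages), naive_final_waking(stages)
    rt = naive_rem_time(stages)
    if not rt:
        return None
    num = sum(counts[i] for i in range(on, fw) if stages[i] == "REM")
    return num / rt


def naive_rd1(stages, counts, gap_counts_wake=True):
    periods = naive_segment(stages, gap_counts_wake)
    if not periods:
        return None
    start, end, rem_min, _ = periods[0]
    num = sum(counts[i] for i in range(start, end) if stages[i] == "REM")
    return num / rem_min


# --- exact test distributions by enumeration --------------------------

def exact_mwu_p(x, y):
    """Two-tailed Mann-Whitney p by enumeration over all group assignments
    of the pooled sample (no ties assumed)."""
    pooled = list(x) + list(y)
    m = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    mu = m * (len(pooled) - m) / 2.0
    dev = abs(u_obs - mu)
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(len(pooled)), m):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def exact_wilcoxon_p(diffs):
    """Two-tailed signed-rank p by enumeration over all 2^n sign patterns
    (zeros removed first, no tied magnitudes assumed)."""
    d = [v for v in diffs if v != 0]
    n = len(d)
    ranks = {}
    for r, i in enumerate(sorted(range(n), key=lambda i: abs(d[i])), start=1):
        ranks[i] = r
    w_obs = sum(ranks[i] for i in range(n) if d[i] > 0)
    mu = n * (n + 1) / 4.0
    dev = abs(w_obs - mu)
    extreme = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(ranks[i] for i in range(n) if signs[i])
        if abs(w - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / 2**n


def stepdown_holm(pvals, alpha=0.05):
    """Direct step-down Holm: adjusted p-values and rejections."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj, [a <= alpha for a in adj]


def rank_auc(scores, labels):
    """AUC via the normalized Mann-Whitney statistic with midranks."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    order = np.argsort(s)
    ranks = np.empty_like(s)
    # midranks for ties
    sorted_s = s[order]
    i = 0
    pos = np.arange(1, s.size + 1, dtype=float)
    while i < s.size:
        j = i
        while j < s.size and sorted_s[j] == sorted_s[i]:
            j += 1
        pos[i:j] = (i + 1 + j) / 2.0
        i = j
    ranks[order] = pos
    r1 = ranks[y == 1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def binormal_auc(delta):
    """Closed-form AUC of two unit-variance normals separated by delta."""
    return 0.5 * (1.0 + math.erf(delta / math.sqrt(2.0) / math.sqrt(2.0)))
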