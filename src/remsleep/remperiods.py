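"""REM-period segmentation and the REM metric panel.

A REM period (REMP) is an episode of REM sleep lasting at least three
minutes; distinct REMPs are separated by fifteen minutes or more of
non-REM.  Segmentation groups REM epochs greedily left to right: REM
epochs whose separation is under 15 minutes belong to one candidate
period, and candidates with under 3 cumulative REM minutes are discarded.
The 3-minute minimum applies to cumulative REM within the candidate, not
the longest consecutive run, since a candidate may contain brief non-REM
interruptions by construction of the 15-minute rule.

On top of the segmentation this module computes the night's REM panel:

* RL (REM latency): minutes from sleep onset to the first REMP, elapsed
  time including any intervening wake.
* REM Time, REM Percent: total REM minutes in the sleep window and their
  share of TST.  REM Time counts all REM epochs, not only those inside
  surviving REMPs.
* REM Efficiency: percent of completed-REMP span actually spent in REM.
  A REMP is *completed* when it is followed by >= 15 min of non-REM
  before final waking; a period truncated by the end of the night is not.
* Total Night RD: eye movements across the night's REM sleep per minute
  of REM time.
* RD1: eye movements in the first REMP per minute of REM within it — the
  first-period REM density, reported in counts/min.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedMetric
from .hypnogram import (
    Hypnogram,
    final_waking,
    sleep_onset,
    sws_minutes,
    sleep_efficiency,
    total_sleep_time,
    waso_minutes,
)

#: 3-minute REMP minimum and 15-minute separation, in epochs.
MIN_REMP_EPOCHS = 6
SEPARATION_EPOCHS = 30


@dataclass(frozen=True)
class REMPeriod:
    """One segmented REM period, in epoch units (half-open ``[start, end)``)."""

    start: int
    end: int
    rem_minutes: float
    span_minutes: float
    completed: bool

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid period bounds")
        if self.rem_minutes < MIN_REMP_EPOCHS * 0.5 - 1e-12:
            raise ValueError("REM period under the 3-minute minimum")
        if self.rem_minutes > self.span_minutes + 1e-12:
            raise ValueError("REM minutes exceed period span")


def _gap_qualifies(stage: str, gap_counts_wake: bool) -> bool:
    """Does this epoch count toward the 15-min separation between REMPs?"""
    if stage in ("S1", "S2", "S3", "S4"):
        return True
    if stage == "W":
        return gap_counts_wake
    return False  # REM handled separately; UNSCORED counts as neither


def segment_rem_periods(
    hyp: Hypnogram, gap_counts_wake: bool = True
) -> list[REMPeriod]:
    """Segment a night into REM periods under the 3-min / 15-min rules.

    ``gap_counts_wake`` controls whether wake epochs accumulate toward the
    15-minute separation (the rule speaks of non-REM *sleep*; counting
    wake as separating time is the default and is recorded in config).
    """
    stages = hyp.stages
    rem_idx = [i for i, s in enumerate(stages) if s == "REM"]
    if not rem_idx:
        return []
    fw = final_waking(hyp)
    assert fw is not None

    # split REM epochs where the qualifying gap reaches 15 minutes
    groups: list[list[int]] = [[rem_idx[0]]]
    for prev, cur in zip(rem_idx, rem_idx[1:]):
        gap = sum(
            1 for j in range(prev + 1, cur) if _gap_qualifies(stages[j], gap_counts_wake)
        )
        if gap >= SEPARATION_EPOCHS:
            groups.append([cur])
        else:
            groups[-1].append(cur)

    periods: list[REMPeriod] = []
    for g in groups:
        if len(g) < MIN_REMP_EPOCHS:
            continue
        start, end = g[0], g[-1] + 1
        # completed iff >= 15 min of qualifying non-REM follows before the
        # next REM epoch or final waking
        tail = 0
        completed = False
        for j in range(end, fw):
            if stages[j] == "REM":
                break
            if _gap_qualifies(stages[j], gap_counts_wake):
                tail += 1
                if tail >= SEPARATION_EPOCHS:
                    completed = True
                    break
        else:
            completed = tail >= SEPARATION_EPOCHS
        periods.append(
            REMPeriod(
                start=start,
                end=end,
                rem_minutes=0.5 * len(g),
                span_minutes=0.5 * (end - start),
                completed=completed,
            )
        )
    return periods


def rem_latency(hyp: Hypnogram, periods: Sequence[REMPeriod]) -> Optional[float]:
    """Minutes from sleep onset to the first REMP; ``None`` if either is absent."""
    onset = sleep_onset(hyp)
    if onset is None or not periods:
        return None
    return 0.5 * (periods[0].start - onset)


def rem_time(hyp: Hypnogram) -> float:
    """Total REM minutes between sleep onset and final waking."""
    onset = sleep_onset(hyp)
    if onset is None:
        raise UndefinedMetric("no sleep onset: REM time undefined")
    fw = final_waking(hyp)
    return 0.5 * sum(1 for s in hyp.stages[onset:fw] if s == "REM")


def rem_percent(hyp: Hypnogram) -> float:
    """REM time as a percentage of total sleep time."""
    tst = total_sleep_time(hyp)
    if tst <= 0:
        raise UndefinedMetric("zero TST: REM percent undefined")
    return 100.0 * rem_time(hyp) / tst


def rem_efficiency(periods: Sequence[REMPeriod]) -> Optional[float]:
    """Percent of completed-REMP span spent in REM; ``None`` with no
    completed period."""
    comp = [p for p in periods if p.completed]
    if not comp:
        return None
    return 100.0 * sum(p.rem_minutes for p in comp) / sum(p.span_minutes for p in comp)


def total_night_rd(
    epoch_counts: np.ndarray, hyp: Hypnogram, numerator_rem_only: bool = True
) -> float:
    """Total-night REM density, counts per minute of REM time.

    The numerator sums eye movements over REM epochs in the sleep window
    (``numerator_rem_only=False`` instead sums every movement of the
    night, a literal reading recorded as a config option); the denominator
    is REM time.
    """
    rt = rem_time(hyp)
    if rt <= 0:
        raise UndefinedMetric("no REM time: REM density undefined")
    counts = np.asarray(epoch_counts)
    onset = sleep_onset(hyp)
    fw = final_waking(hyp)
    if numerator_rem_only:
        num = sum(
            int(counts[i]) for i in range(onset, fw) if hyp.stages[i] == "REM"
        )
    else:
        num = int(counts.sum())
    return num / rt


def rd1(
    epoch_counts: np.ndarray,
    periods: Sequence[REMPeriod],
    hyp: Hypnogram,
) -> Optional[float]:
    """First-REM-period density: movements in the first REMP over its REM
    minutes; ``None`` when the night has no REMP."""
    if not periods:
        return None
    p = periods[0]
    counts = np.asarray(epoch_counts)
    num = sum(
        int(counts[i]) for i in range(p.start, p.end) if hyp.stages[i] == "REM"
    )
    return num / p.rem_minutes


@dataclass
class NightMetrics:
    """The full per-night metric panel.  ``None`` marks a metric whose
    precondition failed for this night (never a silent zero)."""

    rl_minutes: Optional[float]
    rd1: Optional[float]
    total_night_rd: Optional[float]
    tst: Optional[float]
    rem_time: Optional[float]
    rem_percent: Optional[float]
    rem_efficiency: Optional[float]
    sws: Optional[float]
    waso: Optional[float]
    se: Optional[float]

    def to_dict(self) -> dict:
        return asdict(self)

    FIELDS = (
        "rl_minutes", "rd1", "total_night_rd", "tst", "rem_time",
        "rem_percent", "rem_efficiency", "sws", "waso", "se",
    )


def night_metrics(
    hyp: Hypnogram,
    epoch_counts: Optional[np.ndarray] = None,
    gap_counts_wake: bool = True,
    numerator_rem_only: bool = True,
) -> NightMetrics:
    """Assemble the whole panel for one night.

    Eye-movement-based fields (RD1, Total Night RD) are ``None`` when
    ``epoch_counts`` is not supplied.  Per-metric undefined conditions
    are caught and surfaced as ``None``.
    """
    periods = segment_rem_periods(hyp, gap_counts_wake=gap_counts_wake)

    def _try(fn, *args):
        try:
            return fn(*args)
        except UndefinedMetric:
            return None

    counts = epoch_counts
    rd_val = drd1 = None
    if counts is not None:
        rd_val = _try(lambda: total_night_rd(counts, hyp, numerator_rem_only))
        drd1 = rd1(counts, periods, hyp)
    return NightMetrics(
        rl_minutes=rem_latency(hyp, periods),
        rd1=drd1,
        total_night_rd=rd_val,
        tst=_try(total_sleep_time, hyp),
        rem_time=_try(rem_time, hyp),
        rem_percent=_try(rem_percent, hyp),
        rem_efficiency=rem_efficiency(periods),
        sws=_try(sws_minutes, hyp),
        waso=_try(waso_minutes, hyp),
        se=_try(sleep_efficiency, hyp),
    )
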