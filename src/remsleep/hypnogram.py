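"""Scored sleep nights and non-REM-specific architecture metrics.

A night of polysomnography is visually scored in 30-second epochs using the
Rechtschaffen & Kales stage vocabulary: wake (W), stages 1-4 (S1..S4) and REM.
This module holds the :class:`Hypnogram` container and the classical
architecture metrics that do not depend on eye-movement data: sleep onset,
total sleep time (TST), slow-wave sleep (SWS), wake after sleep onset (WASO)
and sleep efficiency (SE).

Conventions
-----------
* The epoch grid is 0-based; intervals are half-open ``[start, end)`` in
  epoch units, and every minute value is ``epoch_count * 0.5``.
* Sleep onset is the first stage-2 epoch.
* "Final waking" is one past the last sleep epoch: terminal wake is excluded
  from WASO, which keeps WASO independent of the lights-on lag.
* UNSCORED epochs count as neither sleep nor wake.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedMetric

#: Rechtschaffen & Kales stage vocabulary.
STAGES = ("W", "S1", "S2", "S3", "S4", "REM", "UNSCORED")
SLEEP_STAGES = frozenset({"S1", "S2", "S3", "S4", "REM"})
NREM_SLEEP_STAGES = frozenset({"S1", "S2", "S3", "S4"})
SWS_STAGES = frozenset({"S3", "S4"})

#: Mapping applied to stage tokens on ingest.  Default maps AASM labels onto
#: the R&K vocabulary (N3 -> S3; S4 is then unused) and common aliases.
DEFAULT_STAGE_MAP = {
    "W": "W", "WAKE": "W", "0": "W",
    "S1": "S1", "N1": "S1", "1": "S1",
    "S2": "S2", "N2": "S2", "2": "S2",
    "S3": "S3", "N3": "S3", "3": "S3",
    "S4": "S4", "4": "S4",
    "REM": "REM", "R": "REM", "5": "REM",
    "UNSCORED": "UNSCORED", "?": "UNSCORED", "MOVEMENT": "UNSCORED",
    "A": "UNSCORED",
}

EPOCH_SECONDS = 30.0


def _clock_span_seconds(lights_out: _dt.time, lights_on: _dt.time) -> float:
    """Span from lights-out to lights-on, wrapping past midnight if needed."""
    out_s = (lights_out.hour * 3600 + lights_out.minute * 60 + lights_out.second)
    on_s = (lights_on.hour * 3600 + lights_on.minute * 60 + lights_on.second)
    span = on_s - out_s
    if span <= 0:
        span += 24 * 3600
    return float(span)


@dataclass(frozen=True)
class Hypnogram:
    """One scored night: an ordered sequence of 30-s epoch stage labels.

    Parameters
    ----------
    stages
        Stage token per epoch, from :data:`STAGES`.
    subject_id
        Opaque subject identifier.
    night
        One of ``adaptation``, ``baseline``, ``post_treatment``.
    lights_out, lights_on
        Session clock anchors.  When both are given, the clock span must
        match ``len(stages) * 30 s`` to within one epoch.
    """

    stages: tuple
    subject_id: str = ""
    night: str = "baseline"
    lights_out: Optional[_dt.time] = None
    lights_on: Optional[_dt.time] = None
    epoch_seconds: float = field(default=EPOCH_SECONDS)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if not self.stages:
            raise ValueError("hypnogram must contain at least one epoch")
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise ValueError(f"unknown stage tokens: {bad}")
        if self.epoch_seconds != EPOCH_SECONDS:
            raise ValueError("epochs are scored in 30-second windows")
        if self.night not in ("adaptation", "baseline", "post_treatment"):
            raise ValueError(f"unknown night label: {self.night!r}")
        if self.lights_out is not None and self.lights_on is not None:
            span = _clock_span_seconds(self.lights_out, self.lights_on)
            if abs(span - len(self.stages) * self.epoch_seconds) > self.epoch_seconds:
                raise ValueError(
                    "lights-out to lights-on span disagrees with the number "
                    f"of scored epochs ({span} s vs {len(self.stages) * 30} s)"
                )

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def in_bed_minutes(self) -> float:
        return len(self.stages) * self.epoch_seconds / 60.0

    def stage_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)


def sleep_onset(hyp: Hypnogram) -> Optional[int]:
    """Index of the first stage-2 epoch, or ``None`` if the night has none."""
    for i, s in enumerate(hyp.stages):
        if s == "S2":
            return i
    return None


def final_waking(hyp: Hypnogram) -> Optional[int]:
    """One past the last sleep epoch (terminal wake excluded); ``None`` if
    the night contains no sleep."""
    for i in range(len(hyp.stages) - 1, -1, -1):
        if hyp.stages[i] in SLEEP_STAGES:
            return i + 1
    return None


def _sleep_window(hyp: Hypnogram) -> tuple[int, int]:
    onset = sleep_onset(hyp)
    if onset is None:
        raise UndefinedMetric("no stage-2 epoch: sleep onset undefined")
    end = final_waking(hyp)
    assert end is not None  # an S2 epoch is itself sleep
    return onset, end


def total_sleep_time(hyp: Hypnogram) -> float:
    """TST in minutes: sleep epochs between sleep onset and final waking."""
    onset, end = _sleep_window(hyp)
    n = sum(1 for s in hyp.stages[onset:end] if s in SLEEP_STAGES)
    return 0.5 * n


def sws_minutes(hyp: Hypnogram) -> float:
    """Slow-wave sleep: minutes of S3 + S4 between onset and final waking."""
    onset, end = _sleep_window(hyp)
    n = sum(1 for s in hyp.stages[onset:end] if s in SWS_STAGES)
    return 0.5 * n


def waso_minutes(hyp: Hypnogram) -> float:
    """Wake after sleep onset, in minutes, terminal wake excluded."""
    onset, end = _sleep_window(hyp)
    n = sum(1 for s in hyp.stages[onset:end] if s == "W")
    return 0.5 * n


def sleep_efficiency(hyp: Hypnogram) -> float:
    """SE in percent: total sleep minutes over in-bed minutes.

    Total sleep here counts every sleep epoch of the record (including any
    before the first S2 epoch); the denominator is the lights-out to
    lights-on span, taken as the scored record length when clock anchors
    are absent.
    """
    if hyp.lights_out is not None and hyp.lights_on is not None:
        in_bed_min = _clock_span_seconds(hyp.lights_out, hyp.lights_on) / 60.0
    else:
        in_bed_min = hyp.in_bed_minutes
    if in_bed_min <= 0:
        raise UndefinedMetric("zero in-bed span")
    sleep_min = 0.5 * sum(1 for s in hyp.stages if s in SLEEP_STAGES)
    return 100.0 * sleep_min / in_bed_min


def map_stages(tokens: Sequence[str], stage_map: Optional[dict] = None) -> list[str]:
    """Map raw stage tokens (e.g. AASM ``N3``) onto the package vocabulary.

    Raises ``ValueError`` listing every unknown token with its row index.
    """
    m = DEFAULT_STAGE_MAP if stage_map is None else stage_map
    out, bad = [], []
    for i, t in enumerate(tokens):
        key = str(t).strip().upper()
        if key in m:
            out.append(m[key])
        else:
            bad.append((i, t))
    if bad:
        listing = ", ".join(f"row {i}: {t!r}" for i, t in bad[:10])
        raise ValueError(f"unknown stage tokens ({len(bad)} rows): {listing}")
    return out
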