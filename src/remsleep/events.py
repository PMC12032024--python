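"""Rapid-eye-movement detection from EOG traces.

Eye movements are detected from the left/right electrooculogram (LOC/ROC)
by an amplitude criterion with no duration criterion: the trace is
band-limited to the saccadic band (0.3-10 Hz by default), and every
excursion between consecutive local extrema whose peak-to-trough amplitude
strictly exceeds the voltage threshold (25 uV by default) becomes a
candidate event.  Candidates on one channel closer than a refractory
interval are collapsed onto the largest one, so a single saccade never
yields multiple events.

Counting movements rather than channel deflections requires a binocular
merge: a saccade appears on both EOG channels near-simultaneously, so
events from different channels within a short coincidence window are
counted once (see :func:`merge_binocular`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import SamplingRateTooLow
from .hypnogram import Hypnogram

DEFAULT_THRESHOLD_UV = 25.0
DEFAULT_REFRACTORY_S = 0.1
DEFAULT_BAND_HZ = (0.3, 10.0)
DEFAULT_COINCIDENCE_S = 0.2


@dataclass(frozen=True)
class EogTrace:
    """One EOG channel: a voltage series aligned to hypnogram epoch 0.

    ``start_offset_s`` is the time of the first sample relative to epoch 0;
    it must be an integer number of samples.
    """

    samples: np.ndarray          # uV
    sampling_rate: float         # Hz
    channel: str = "LOC"         # LOC or ROC
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("empty EOG trace")
        if self.channel not in ("LOC", "ROC"):
            raise ValueError(f"unknown EOG channel {self.channel!r}")
        n_off = self.start_offset_s * self.sampling_rate
        if abs(n_off - round(n_off)) > 1e-6:
            raise ValueError("alignment offset must be a whole number of samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class EyeMovementEvent:
    """One detected rapid eye movement."""

    time_s: float        # seconds from hypnogram epoch 0
    amplitude_uv: float  # peak-to-trough deflection
    channel: str


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    sos = _signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, x)


def _local_extrema(x: np.ndarray) -> np.ndarray:
    """Indices of local extrema of ``x``, endpoints included."""
    d = np.diff(x)
    sgn = np.sign(d)
    # propagate through flat runs so plateaus do not fabricate extrema
    for i in range(1, sgn.size):
        if sgn[i] == 0:
            sgn[i] = sgn[i - 1]
    turns = np.nonzero(np.diff(sgn) != 0)[0] + 1
    return np.concatenate(([0], turns, [x.size - 1]))


def detect_eye_movements(
    trace: EogTrace,
    threshold_uv: float = DEFAULT_THRESHOLD_UV,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    band_hz: tuple[float, float] | None = DEFAULT_BAND_HZ,
) -> list[EyeMovementEvent]:
    """Detect supra-threshold eye movements on one EOG channel.

    An event is an excursion between consecutive local extrema of the
    band-limited trace whose amplitude is *strictly* greater than
    ``threshold_uv`` (a deflection of exactly 25 uV is not an event).
    ``band_hz=None`` skips filtering for traces that are already
    band-limited.  Refractory suppression keeps the largest excursion
    among candidates closer than ``refractory_s``; because a suppressor
    is always at least as large as what it suppresses, raising the
    threshold can never increase the event count.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    if band_hz is None:
        x = trace.samples
    else:
        if trace.sampling_rate < 2.0 * band_hz[1]:
            raise SamplingRateTooLow(
                f"sampling rate {trace.sampling_rate} Hz < 2 x band edge {band_hz[1]} Hz"
            )
        x = _bandpass(trace.samples, trace.sampling_rate, band_hz)
    ext = _local_extrema(x)
    if ext.size < 2:
        return []
    amps = np.abs(np.diff(x[ext]))
    mids = (ext[:-1] + ext[1:]) / 2.0
    keep = amps > threshold_uv
    cand_t = trace.start_offset_s + mids[keep] / trace.sampling_rate
    cand_a = amps[keep]

    # non-maximum suppression within the refractory interval
    order = np.argsort(-cand_a, kind="stable")
    taken: list[tuple[float, float]] = []
    for i in order:
        t, a = cand_t[i], cand_a[i]
        if all(abs(t - t0) > refractory_s for t0, _ in taken):
            taken.append((t, a))
    taken.sort()
    return [EyeMovementEvent(t, a, trace.channel) for t, a in taken]


def merge_binocular(
    events: list[EyeMovementEvent],
    coincidence_s: float = DEFAULT_COINCIDENCE_S,
) -> list[EyeMovementEvent]:
    """Collapse LOC/ROC detections of the same saccade into one movement.

    Events from *different* channels within ``coincidence_s`` are merged,
    keeping the larger amplitude.  Same-channel events are left to the
    detector's refractory handling.  Never adds events.
    """
    pool = sorted(events, key=lambda e: (-e.amplitude_uv, e.time_s, e.channel))
    kept: list[EyeMovementEvent] = []
    for ev in pool:
        dup = any(
            k.channel != ev.channel and abs(k.time_s - ev.time_s) <= coincidence_s
            for k in kept
        )
        if not dup:
            kept.append(ev)
    kept.sort(key=lambda e: e.time_s)
    return kept


def count_events_by_epoch(
    events: list[EyeMovementEvent],
    hyp: Hypnogram,
    coincidence_s: float = DEFAULT_COINCIDENCE_S,
    deduplicate: bool = True,
) -> np.ndarray:
    """Bin eye movements onto the hypnogram's 30-s epoch grid.

    Returns an integer vector of length ``len(hyp)``; an event at time ``t``
    increments epoch ``floor(t / 30)``.  LOC/ROC duplicates are merged first
    (one saccade, one count).  Events outside the recording span are dropped
    with a warning; the binned total therefore never exceeds the raw count.
    """
    if deduplicate:
        events = merge_binocular(events, coincidence_s)
    counts = np.zeros(len(hyp), dtype=int)
    span_s = len(hyp) * hyp.epoch_seconds
    rejected = 0
    for ev in events:
        if 0.0 <= ev.time_s < span_s:
            counts[int(ev.time_s // hyp.epoch_seconds)] += 1
        else:
            rejected += 1
    if rejected:
        warnings.warn(
            f"{rejected} eye-movement event(s) outside the {span_s:.0f}-s "
            "recording span were dropped",
            stacklevel=2,
        )
    return counts
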