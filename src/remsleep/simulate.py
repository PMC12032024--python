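"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-group polysomnography study — a
treatment-resistant-depression (TRD) group recorded at baseline and after
a single ketamine infusion, and healthy volunteers (HV) recorded at
baseline — so that every pipeline stage is testable without clinical
data.  It produces, per subject-night:

* a hypnogram built from a semi-Markov episode model: sleep latency,
  a first NREM segment whose length is the drawn REM latency, then
  alternating REM episodes (lengthening across cycles) and NREM gaps of
  at least 16 minutes, with Bernoulli wake intrusions in NREM, brief
  non-REM interruptions inside REM episodes, slow-wave sleep
  front-loaded into the first cycles, and a terminal wake tail;
* an eye-movement train: homogeneous Poisson within each REM epoch at a
  subject-level base rate modulated by a first-period multiplier.  The
  TRD multiplier raises first-period density (RD1) and the HV multiplier
  lowers it, while a compensating late-night rate preserves each
  subject's night-average density — so RD1 separates the groups while
  Total Night RD does not, the study's baseline pattern.  Post-treatment
  nights shrink the TRD first-period multiplier (ketamine lowers RD1)
  and lengthen REM episodes (REM time rises), again compensated so the
  night-average density is unchanged;
* optionally, a pair of EOG traces with biphasic deflections implanted
  at the event times plus Gaussian noise, for detector testing;
* HAM-D scores: truncated-normal baseline (>= 17), a responder indicator
  drawn from a logistic link on baseline RD1 (calibrated so the expected
  responder count matches the target), and a day-1 score consistent with
  the >= 50%-reduction rule.  A configurable number of subjects lack the
  day-1 score, emulating missing response data.

Group separations are calibration choices of this generator, not
estimates of the study's effect sizes; see the methods note.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .events import EogTrace, EyeMovementEvent, count_events_by_epoch
from .hypnogram import Hypnogram
from .remperiods import NightMetrics, night_metrics, segment_rem_periods


def _lognormal_params(mean: float, sigma_log: float) -> tuple[float, float]:
    """(mu, sigma) of ln X for a lognormal with the given arithmetic mean."""
    return math.log(mean) - 0.5 * sigma_log**2, sigma_log


@dataclass
class GroupLatencyModel:
    """Lognormal REM-latency model for one group (minutes)."""

    mean: float
    sigma_log: float
    minimum: float = 20.0  # floor, keeps the first cycle physiologic

    def draw(self, rng: np.random.Generator) -> float:
        mu, s = _lognormal_params(self.mean, self.sigma_log)
        return max(self.minimum, float(rng.lognormal(mu, s)))

    def expected(self, n_mc: int = 200_000, seed: int = 12345) -> float:
        """Mean of the floored lognormal (Monte-Carlo; the floor makes the
        closed form awkward)."""
        mu, s = _lognormal_params(self.mean, self.sigma_log)
        x = np.random.default_rng(seed).lognormal(mu, s, size=n_mc)
        return float(np.maximum(self.minimum, x).mean())


@dataclass
class CohortSpec:
    """Study-shaped generator configuration.

    Defaults emulate the study cohort: 63 TRD (of whom 2 lack response
    data, leaving 20 responders / 41 non-responders) and 41 HV; elevated
    first-period REM density and shortened REM latency in TRD with equal
    night-average density; a post-ketamine RD1 reduction and REM-time
    increase in TRD.
    """

    n_trd: int = 63
    n_hv: int = 41
    n_responders: int = 20
    n_missing_response: int = 2
    seed: int = 0

    # --- stage model -------------------------------------------------
    in_bed_minutes: float = 480.0
    sleep_latency_mean: float = 15.0     # min, normal, truncated >= 1
    sleep_latency_sd: float = 8.0
    latency_trd: GroupLatencyModel = field(
        default_factory=lambda: GroupLatencyModel(mean=60.0, sigma_log=0.35))
    latency_hv: GroupLatencyModel = field(
        default_factory=lambda: GroupLatencyModel(mean=90.0, sigma_log=0.30))
    rem_episode_means: tuple = (14.0, 20.0, 26.0, 30.0)   # min, per cycle
    rem_episode_sd: float = 3.0
    rem_episode_min: float = 4.0
    nrem_gap_mean: float = 50.0          # min between REM episodes
    nrem_gap_sd: float = 8.0
    nrem_gap_min: float = 16.0           # keeps REMPs distinct (>= 15-min rule)
    wake_intrusion_prob: float = 0.10    # per NREM epoch -> WASO ~ 35 min
    rem_interruption_prob: float = 0.05  # per interior REM epoch -> efficiency ~95%
    sws_mean: float = 25.0               # min, front-loaded S3/S4
    sws_sd: float = 12.0
    terminal_wake_mean: float = 10.0     # min
    terminal_wake_sd: float = 5.0
    lights_out: _dt.time = _dt.time(23, 0, 0)

    # --- eye-movement model -----------------------------------------
    em_base_rate_trd: float = 1.2        # counts per REM minute, night average
    em_base_rate_hv: float = 1.2         # equal by design: Total Night RD group-flat
    em_rate_cv: float = 0.5              # between-subject lognormal CV
    rd1_multiplier_trd: float = 4.0 / 3.0   # -> E[RD1] = 1.6 at baseline
    rd1_multiplier_hv: float = 2.0 / 3.0    # -> E[RD1] = 0.8
    treatment_rd1_factor: float = 0.75   # ketamine lowers RD1 by 25%
    treatment_rem_time_factor: float = 1.15  # REM time ~90 -> ~103 min

    # --- clinical model ---------------------------------------------
    hamd_mean: float = 21.45
    hamd_sd: float = 3.98
    hamd_min: float = 17.0
    response_link_slope: float = 1.5     # logit units per counts/min of RD1
    response_threshold: float = 0.50

    def __post_init__(self) -> None:
        if min(self.n_trd, self.n_hv) <= 0:
            raise ValueError("group sizes must be positive")
        if not (0 <= self.n_responders <= self.n_trd - self.n_missing_response):
            raise ValueError("responder target exceeds labeled TRD subjects")
        if min(self.em_base_rate_trd, self.em_base_rate_hv) < 0:
            raise ValueError("rates must be non-negative")

    def latency_model(self, group: str) -> GroupLatencyModel:
        return self.latency_trd if group == "TRD" else self.latency_hv

    def base_rate(self, group: str) -> float:
        return self.em_base_rate_trd if group == "TRD" else self.em_base_rate_hv

    def rd1_multiplier(self, group: str, night: str) -> float:
        m = self.rd1_multiplier_trd if group == "TRD" else self.rd1_multiplier_hv
        if group == "TRD" and night == "post_treatment":
            m *= self.treatment_rd1_factor
        return m

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lights_out"] = self.lights_out.isoformat()
        return d


def _minutes_to_epochs(minutes: float) -> int:
    return max(0, int(round(minutes * 2.0)))


def simulate_hypnogram(
    spec: CohortSpec, group: str, night: str, rng: np.random.Generator
) -> Hypnogram:
    """Draw one night's hypnogram from the semi-Markov episode model."""
    n_epochs = _minutes_to_epochs(spec.in_bed_minutes)
    lat_model = spec.latency_model(group)
    rl_min = lat_model.draw(rng)
    rem_factor = (
        spec.treatment_rem_time_factor
        if (group == "TRD" and night == "post_treatment")
        else 1.0
    )

    # pre-onset: wake then one S1 epoch, then the anchored S2 onset epoch
    pre = max(1.0, rng.normal(spec.sleep_latency_mean, spec.sleep_latency_sd))
    n_pre = max(1, _minutes_to_epochs(pre))
    stages: list[str] = ["W"] * (n_pre - 1) + ["S1"]

    terminal = max(0.0, rng.normal(spec.terminal_wake_mean, spec.terminal_wake_sd))
    n_terminal = _minutes_to_epochs(terminal)
    budget = n_epochs - n_terminal  # epochs available for the sleep body

    nrem_segments: list[int] = []   # indices into `stages` eligible for intrusions/SWS
    sws_eligible: list[int] = []

    def _extend_nrem(n: int, cycle: int) -> None:
        for k in range(n):
            if len(stages) >= budget:
                return
            idx = len(stages)
            stages.append("S2")
            if k > 0:  # protect segment-leading epoch (keeps onset/gap anchors)
                nrem_segments.append(idx)
                if cycle < 2:
                    sws_eligible.append(idx)

    # first NREM segment: its length *is* the REM latency
    _extend_nrem(_minutes_to_epochs(rl_min), cycle=0)

    cycle = 0
    means = spec.rem_episode_means
    while len(stages) < budget:
        dur = max(
            spec.rem_episode_min,
            rng.normal(means[min(cycle, len(means) - 1)] * rem_factor,
                       spec.rem_episode_sd),
        )
        n_rem = _minutes_to_epochs(dur)
        n_rem = min(n_rem, budget - len(stages))
        if n_rem <= 0:
            break
        start = len(stages)
        for j in range(n_rem):
            interior = 0 < j < n_rem - 1
            if interior and rng.random() < spec.rem_interruption_prob:
                stages.append("S2")
            else:
                stages.append("REM")
        cycle += 1
        if cycle >= len(means):
            # fill the remainder of the night with NREM
            _extend_nrem(budget - len(stages), cycle)
            break
        gap = max(spec.nrem_gap_min,
                  rng.normal(spec.nrem_gap_mean, spec.nrem_gap_sd))
        _extend_nrem(_minutes_to_epochs(gap), cycle)

    if len(stages) < budget:
        _extend_nrem(budget - len(stages), cycle=max(cycle, 2))

    # slow-wave sleep: convert leading eligible S2 epochs of the first cycles
    n_sws = _minutes_to_epochs(max(0.0, rng.normal(spec.sws_mean, spec.sws_sd)))
    for i, idx in enumerate(sws_eligible[:n_sws]):
        stages[idx] = "S3" if i % 2 == 0 else "S4"

    # wake intrusions in NREM (never on protected anchor epochs)
    for idx in nrem_segments:
        if stages[idx] == "S2" and rng.random() < spec.wake_intrusion_prob:
            stages[idx] = "W"

    stages.extend(["W"] * (n_epochs - len(stages)))
    lights_on_s = (
        spec.lights_out.hour * 3600 + spec.lights_out.minute * 60
        + spec.lights_out.second + n_epochs * 30
    ) % (24 * 3600)
    lights_on = _dt.time(lights_on_s // 3600, (lights_on_s % 3600) // 60,
                         lights_on_s % 60)
    return Hypnogram(
        stages=tuple(stages[:n_epochs]),
        night=night,
        lights_out=spec.lights_out,
        lights_on=lights_on,
    )


def draw_subject_rate(spec: CohortSpec, group: str, rng: np.random.Generator) -> float:
    """Subject-level night-average eye-movement rate (counts/REM-minute)."""
    base = spec.base_rate(group)
    if base <= 0:
        return 0.0
    cv = spec.em_rate_cv
    sigma = math.sqrt(math.log(1.0 + cv**2))
    mu = math.log(base) - 0.5 * sigma**2
    return float(rng.lognormal(mu, sigma))


def simulate_em_events(
    hyp: Hypnogram,
    spec: CohortSpec,
    group: str,
    night: str,
    rng: np.random.Generator,
    base_rate: float | None = None,
) -> list[EyeMovementEvent]:
    """Poisson eye-movement train over the night's REM epochs.

    The first REM period runs at ``base_rate * multiplier``; later REM
    epochs run at the compensating rate that preserves the night-average
    density, so group/treatment effects live in RD1 but not in Total
    Night RD.
    """
    lam = draw_subject_rate(spec, group, rng) if base_rate is None else base_rate
    periods = segment_rem_periods(hyp)
    rem_epochs = [i for i, s in enumerate(hyp.stages) if s == "REM"]
    if not rem_epochs or lam <= 0:
        return []
    first = set(range(periods[0].start, periods[0].end)) if periods else set()
    first_rem = [i for i in rem_epochs if i in first]
    n_first, n_total = len(first_rem), len(rem_epochs)
    m1 = spec.rd1_multiplier(group, night)
    f = n_first / n_total
    m_late = (1.0 - f * m1) / (1.0 - f) if f < 1.0 else m1
    m_late = max(0.0, m_late)

    events: list[EyeMovementEvent] = []
    for i in rem_epochs:
        rate = lam * (m1 if i in first else m_late)  # per minute
        k = rng.poisson(rate * 0.5)
        if k:
            times = i * 30.0 + rng.uniform(0.0, 30.0, size=k)
            amps = 30.0 + rng.gamma(4.0, 5.0, size=k)  # uV, all supra-threshold
            events.extend(
                EyeMovementEvent(float(t), float(a), "LOC")
                for t, a in zip(np.sort(times), amps)
            )
    return events


def simulate_eog(
    events: list[EyeMovementEvent],
    duration_s: float,
    noise_sd_uv: float = 3.0,
    sampling_rate: float = 200.0,
    rng: np.random.Generator | None = None,
    amplitudes_uv: np.ndarray | None = None,
    deflection_s: float = 0.35,
) -> tuple[EogTrace, EogTrace]:
    """Render an event train as a pair of noisy EOG traces.

    Each event becomes one biphasic (single-cycle sine) deflection of the
    drawn peak-to-trough amplitude on both channels, anti-phase between
    left and right as conjugate eye movements are; independent Gaussian
    noise is added per channel.  The input events are the ground truth.
    """
    rng = rng or np.random.default_rng()
    n = int(round(duration_s * sampling_rate))
    base = np.zeros(n)
    n_defl = int(round(deflection_s * sampling_rate))
    t = np.arange(n_defl) / sampling_rate
    shape = np.sin(2.0 * np.pi * t / deflection_s)
    for k, ev in enumerate(events):
        amp = ev.amplitude_uv if amplitudes_uv is None else float(amplitudes_uv[k])
        i0 = int(round(ev.time_s * sampling_rate))
        i1 = min(n, i0 + n_defl)
        if i0 >= n:
            continue
        base[i0:i1] += 0.5 * amp * shape[: i1 - i0]
    loc = base + rng.normal(0.0, noise_sd_uv, size=n)
    roc = -base + rng.normal(0.0, noise_sd_uv, size=n)
    return (
        EogTrace(loc, sampling_rate, channel="LOC"),
        EogTrace(roc, sampling_rate, channel="ROC"),
    )


def simulate_clinical(
    spec: CohortSpec,
    rd1_baseline: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """HAM-D trajectories and responder labels for the TRD subjects.

    The response probability follows a logistic link on baseline RD1,
    with the intercept solved so the expected responder count among
    labeled subjects equals ``spec.n_responders``.  Day-1 scores are
    integers consistent with the inclusive >= 50%-reduction rule.
    """
    rd1 = np.asarray(rd1_baseline, dtype=float)
    n = rd1.size
    baseline = np.empty(n)
    for i in range(n):  # truncated normal >= hamd_min, by rejection
        while True:
            v = rng.normal(spec.hamd_mean, spec.hamd_sd)
            if v >= spec.hamd_min:
                baseline[i] = v
                break
    baseline = np.round(baseline)

    missing = rng.choice(n, size=min(spec.n_missing_response, n), replace=False)
    labeled = np.setdiff1d(np.arange(n), missing)
    b = spec.response_link_slope
    xc = rd1[labeled] - rd1[labeled].mean() if labeled.size else rd1

    def _expected(a: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(a + b * xc)))).sum()) - spec.n_responders

    if labeled.size and 0 < spec.n_responders < labeled.size:
        a = brentq(_expected, -50.0, 50.0)
    else:
        a = -50.0 if spec.n_responders == 0 else 50.0
    prob = 1.0 / (1.0 + np.exp(-(a + b * xc)))
    resp = rng.random(labeled.size) < prob

    day1 = np.full(n, np.nan)
    responder = np.array([None] * n, dtype=object)
    for j, i in enumerate(labeled):
        if resp[j]:
            frac = rng.uniform(spec.response_threshold, 0.85)
            day1[i] = math.floor(baseline[i] * (1.0 - frac))
        else:
            frac = rng.uniform(0.0, spec.response_threshold - 0.05)
            day1[i] = math.ceil(baseline[i] * (1.0 - frac))
        responder[i] = bool(
            (baseline[i] - day1[i]) / baseline[i] >= spec.response_threshold
        )
    return pd.DataFrame(
        {
            "hamd_baseline": baseline,
            "hamd_day1": day1,
            "responder": responder,
        }
    )


def simulate_cohort(
    spec: CohortSpec,
    keep_raw: bool = False,
    events_for_hv: bool = True,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Generate the full cohort table: one row per subject-night.

    TRD subjects get baseline and post-treatment nights; HV subjects get
    a baseline night only.  The returned frame carries subject id, group,
    night, the ten metric-panel columns, and the clinical columns for
    TRD.  With ``keep_raw=True`` a dict of the underlying hypnograms and
    event trains is returned alongside.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    raw: dict[tuple[str, str], dict] = {}
    trd_rd1: dict[str, float] = {}

    plan = [("TRD", i) for i in range(spec.n_trd)] + [("HV", i) for i in range(spec.n_hv)]
    for group, i in plan:
        sid = f"{group.lower()}{i:03d}"
        lam = draw_subject_rate(spec, group, rng)
        nights = ["baseline", "post_treatment"] if group == "TRD" else ["baseline"]
        for night in nights:
            drawn = simulate_hypnogram(spec, group, night, rng)
            hyp = Hypnogram(
                stages=drawn.stages, subject_id=sid, night=night,
                lights_out=drawn.lights_out, lights_on=drawn.lights_on,
            )
            ev = (
                simulate_em_events(hyp, spec, group, night, rng, base_rate=lam)
                if (group == "TRD" or events_for_hv)
                else []
            )
            counts = count_events_by_epoch(ev, hyp)
            nm = night_metrics(hyp, counts)
            row = {"subject_id": sid, "group": group, "night": night}
            row.update(nm.to_dict())
            rows.append(row)
            if keep_raw:
                raw[(sid, night)] = {"hypnogram": hyp, "events": ev}
            if group == "TRD" and night == "baseline":
                trd_rd1[sid] = nm.rd1 if nm.rd1 is not None else 0.0

    cohort = pd.DataFrame(rows)
    trd_ids = sorted(trd_rd1)
    clin = simulate_clinical(
        spec, np.array([trd_rd1[s] for s in trd_ids]), rng
    )
    clin.insert(0, "subject_id", trd_ids)
    cohort = cohort.merge(clin, on="subject_id", how="left")
    return (cohort, raw) if keep_raw else cohort


def _lights_on(lights_out: _dt.time, n_epochs: int) -> _dt.time:
    s = (lights_out.hour * 3600 + lights_out.minute * 60 + lights_out.second
         + n_epochs * 30) % (24 * 3600)
    return _dt.time(s // 3600, (s % 3600) // 60, s % 60)
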