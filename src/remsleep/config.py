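"""Declarative run configuration.

Every defaulted analysis decision made elsewhere in the package is
surfaced here explicitly — detector band/refractory/coincidence settings,
segmentation flags (whether wake counts toward the 15-minute separation,
whether the density numerators are restricted to REM epochs), statistics
alpha and the two correction families, the prediction harness settings
and the generator spec — so a run is fully described by one serializable
object.  The configuration hash names every output file of a run, and a
run can be regenerated exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .predict import PredictionConfig
from .simulate import CohortSpec, GroupLatencyModel
from .stats import ALPHA_DEFAULT, BASELINE_FAMILY, TREATMENT_FAMILY


@dataclass
class DetectorConfig:
    threshold_uv: float = 25.0
    refractory_s: float = 0.1
    band_hz: tuple = (0.3, 10.0)
    coincidence_s: float = 0.2
    require_antiphase: bool = False  # binocular merge ignores polarity by default


@dataclass
class SegmentationConfig:
    gap_counts_wake: bool = True
    numerator_rem_only: bool = True


@dataclass
class StatsConfig:
    alpha: float = ALPHA_DEFAULT
    baseline_family: tuple = BASELINE_FAMILY
    treatment_family: tuple = TREATMENT_FAMILY


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "remsleep_out"
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    #: directory of hypnogram/event/clinical CSVs; None -> simulate the cohort
    input_dir: str | None = None

    def __post_init__(self) -> None:
        # one seed drives everything unless sub-seeds are set explicitly
        self.cohort.seed = self.cohort.seed or self.seed
        self.prediction.seed = self.prediction.seed or self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["lights_out"] = self.cohort.lights_out.isoformat()
        return d

    def config_hash(self) -> str:
        """Short stable digest of the full configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return config_from_dict(d)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d or {})
    det = DetectorConfig(**{**{}, **d.get("detector", {})})
    det.band_hz = tuple(det.band_hz)
    seg = SegmentationConfig(**d.get("segmentation", {}))
    st = d.get("stats", {})
    stats = StatsConfig(
        alpha=st.get("alpha", ALPHA_DEFAULT),
        baseline_family=tuple(st.get("baseline_family", BASELINE_FAMILY)),
        treatment_family=tuple(st.get("treatment_family", TREATMENT_FAMILY)),
    )
    pred = PredictionConfig(**d.get("prediction", {}))
    co = dict(d.get("cohort", {}))
    if "lights_out" in co and isinstance(co["lights_out"], str):
        co["lights_out"] = _dt.time.fromisoformat(co["lights_out"])
    for key in ("latency_trd", "latency_hv"):
        if key in co and isinstance(co[key], dict):
            co[key] = GroupLatencyModel(**co[key])
    if "rem_episode_means" in co:
        co["rem_episode_means"] = tuple(co["rem_episode_means"])
    cohort = CohortSpec(**co)
    return RunConfig(
        seed=d.get("seed", 0),
        output_dir=d.get("output_dir", "remsleep_out"),
        detector=det,
        segmentation=seg,
        stats=stats,
        prediction=pred,
        cohort=cohort,
        input_dir=d.get("input_dir"),
    )
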