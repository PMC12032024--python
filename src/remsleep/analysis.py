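"""End-to-end orchestration of the three analyses.

``run_analysis`` ties the stages together on a cohort table (simulated or
loaded from CSVs): the baseline group comparison of the REM markers
(RL, RD1, Total Night RD), the within-TRD treatment comparison of the
additional sleep variables, and the RD1-based response-prediction
harness.  It emits mean +/- SEM summary tables, test-result tables, the
prediction report with ROC points, a normality report, and a provenance
manifest (config hash, seed, package versions).  Identical configuration
yields byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, save_config
from .errors import DegenerateSample
from .events import count_events_by_epoch
from .io import read_clinical_file, read_events_file, read_hypnogram_file
from .predict import holdout_validate
from .remperiods import NightMetrics, night_metrics
from .stats import (
    TestResult,
    adjust_family,
    compare_groups,
    compare_paired,
    normality_gate,
    summary_table,
)
from .simulate import simulate_cohort

log = logging.getLogger("remsleep")

METRIC_COLUMNS = list(NightMetrics.FIELDS)


def metrics_from_files(hypnogram_paths, event_paths=None, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Compute the metric panel for a set of hypnogram CSVs (plus optional
    matching event CSVs, paired by order)."""
    cfg = cfg or RunConfig()
    rows = []
    event_paths = list(event_paths) if event_paths else [None] * len(list(hypnogram_paths))
    for hp, ep in zip(hypnogram_paths, event_paths):
        hyp = read_hypnogram_file(hp)
        counts = None
        if ep is not None:
            events = read_events_file(ep)
            counts = count_events_by_epoch(
                events, hyp, coincidence_s=cfg.detector.coincidence_s
            )
        nm = night_metrics(
            hyp,
            counts,
            gap_counts_wake=cfg.segmentation.gap_counts_wake,
            numerator_rem_only=cfg.segmentation.numerator_rem_only,
        )
        rows.append(
            {"subject_id": hyp.subject_id, "night": hyp.night} | nm.to_dict()
        )
    return pd.DataFrame(rows)


def _load_cohort(cfg: RunConfig) -> pd.DataFrame:
    indir = Path(cfg.input_dir)
    hyps = sorted(indir.glob("hypnograms/*.csv"))
    evs = {p.stem: p for p in sorted(indir.glob("events/*.csv"))}
    metrics = metrics_from_files(hyps, [evs.get(p.stem) for p in hyps], cfg)
    clinical = read_clinical_file(indir / "clinical.csv")
    return metrics.merge(clinical, on="subject_id", how="left")


def _results_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "test": r.test,
                "statistic": r.statistic,
                "z": r.z,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "method": r.method,
                "n": "/".join(str(v) for v in r.n),
                "direction": r.effect_direction,
            }
            for r in results
        ]
    )


def run_analysis(cfg: RunConfig, write: bool = True) -> dict:
    """Run the full pipeline under one configuration.

    Returns a bundle dict with the cohort table, summary tables, test
    tables, normality report and prediction report; with ``write=True``
    the bundle is also written under ``cfg.output_dir`` with every file
    name carrying the configuration hash.
    """
    t0 = time.perf_counter()
    if cfg.input_dir is not None:
        cohort = _load_cohort(cfg)
        if "responder" not in cohort.columns:
            cohort["responder"] = pd.array(
                [
                    (b - d) / b >= cfg.prediction.response_threshold
                    if (b == b and d == d and b > 0)
                    else None
                    for b, d in zip(cohort["hamd_baseline"], cohort["hamd_day1"])
                ],
                dtype="object",
            )
    else:
        cohort = simulate_cohort(cfg.cohort)
    log.info("cohort ready: %d rows (%.1fs)", len(cohort), time.perf_counter() - t0)

    bundle: dict = {"cohort": cohort, "config_hash": cfg.config_hash()}

    # --- summaries and normality report ------------------------------
    bundle["summary"] = summary_table(cohort, METRIC_COLUMNS, ("group", "night"))
    norm_rows = []
    for (group, night), g in cohort.groupby(["group", "night"], observed=True):
        for m in METRIC_COLUMNS:
            try:
                r = normality_gate(g[m].dropna(), metric=m, group=f"{group}/{night}")
                norm_rows.append(vars(r))
            except DegenerateSample:
                continue
    bundle["normality"] = pd.DataFrame(norm_rows)

    # --- baseline group comparison (Mann-Whitney + Holm) --------------
    baseline_results = [
        compare_groups(cohort, m, night="baseline")
        for m in cfg.stats.baseline_family
    ]
    adjust_family(baseline_results, alpha=cfg.stats.alpha)
    bundle["baseline_tests"] = _results_frame(baseline_results)

    # --- treatment comparison (Wilcoxon + Holm), if post nights exist --
    has_post = (cohort["night"] == "post_treatment").any()
    if has_post:
        paired_results = []
        for m in cfg.stats.treatment_family:
            try:
                paired_results.append(compare_paired(cohort, m))
            except DegenerateSample as exc:
                log.warning("paired test for %s skipped: %s", m, exc)
        rd1_paired = compare_paired(cohort, "rd1")
        total_rd_paired = compare_paired(cohort, "total_night_rd")
        if paired_results:
            adjust_family(paired_results, alpha=cfg.stats.alpha)
        bundle["treatment_tests"] = _results_frame(paired_results)
        bundle["rem_marker_treatment_tests"] = _results_frame(
            adjust_family([rd1_paired, total_rd_paired,
                           compare_paired(cohort, "rl_minutes")],
                          alpha=cfg.stats.alpha)
        )
    else:
        log.warning("no post-treatment nights: paired analysis skipped")
        bundle["treatment_tests"] = None
        bundle["rem_marker_treatment_tests"] = None

    # --- response prediction ------------------------------------------
    trd_base = cohort[(cohort["group"] == "TRD") & (cohort["night"] == "baseline")]
    labeled = trd_base[trd_base["responder"].notna() & trd_base["rd1"].notna()]
    if labeled["responder"].astype(bool).nunique() == 2:
        report = holdout_validate(
            labeled["rd1"].to_numpy(dtype=float),
            labeled["responder"].astype(bool).to_numpy().astype(int),
            cfg.prediction,
        )
        bundle["prediction"] = report
    else:
        log.warning("response prediction skipped: need both classes")
        bundle["prediction"] = None

    if write:
        _write_bundle(bundle, cfg)
    log.info("analysis done in %.1fs", time.perf_counter() - t0)
    return bundle


def _write_bundle(bundle: dict, cfg: RunConfig) -> None:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = bundle["config_hash"]

    def p(name: str) -> Path:
        return outdir / f"{h}_{name}"

    bundle["cohort"].to_csv(p("cohort_metrics.csv"), index=False)
    bundle["summary"].to_csv(p("summary.csv"), index=False)
    bundle["normality"].to_csv(p("normality.csv"), index=False)
    bundle["baseline_tests"].to_csv(p("tests_baseline.csv"), index=False)
    if bundle["treatment_tests"] is not None:
        bundle["treatment_tests"].to_csv(p("tests_treatment.csv"), index=False)
        bundle["rem_marker_treatment_tests"].to_csv(
            p("tests_treatment_rem_markers.csv"), index=False
        )
    if bundle["prediction"] is not None:
        rep = bundle["prediction"]
        with open(p("prediction.json"), "w") as fh:
            json.dump(rep.to_dict(), fh, indent=1, sort_keys=True)
        pd.DataFrame({"fpr": rep.roc_fpr, "tpr": rep.roc_tpr}).to_csv(
            p("roc_points.csv"), index=False
        )
    manifest = {
        "config_hash": h,
        "seed": cfg.seed,
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    save_config(cfg, p("config.yaml"))
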