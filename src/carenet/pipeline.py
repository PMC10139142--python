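"""End-to-end orchestration: records -> events -> networks -> features ->
clusters -> associations -> report tables.

The pipeline is a pure function of (records, facility description,
configuration): identical inputs and seed yield byte-identical outputs.  Each
stage writes its artifact before the next runs, so a failing stage leaves
earlier outputs in place, and failures are re-raised tagged with the stage
name.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import association_table
from .clustering import (
    build_feature_matrix,
    cluster_by_bedroom_table,
    elbow_select,
    flag_extremes,
    kmeans_sweep,
    label_clusters,
)
from .copresence import (
    CleaningReport,
    clean_records,
    count_alone_episodes,
    detect_interactions,
    read_records,
    records_to_intervals,
)
from .facility import DEFAULT_VISIBILITY_CODING, Facility, assess_facility
from .networks import (
    FEATURE_COLUMNS,
    build_two_mode,
    compute_features,
    export_network,
    project_one_mode,
    summarize_by_group,
)
from .report import (
    association_report,
    cluster_means_table,
    contingency_table,
    network_summary_table,
    participant_table,
    privacy_table,
    render_text,
)

__all__ = ["RunConfig", "PipelineResult", "PipelineError", "run_pipeline"]

log = logging.getLogger("carenet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``window_days`` is the number of sampled 24 h days the stream covers; it
    is the denominator of all per-day frequencies.
    """

    records_path: str | Path | None = None
    facility_path: str | Path | None = None
    output_dir: str | Path = "carenet_out"
    window_days: float = 1.0
    min_duration_s: int = 300
    max_gap_s: int = 60
    clean_window_s: int = 30
    k_range: tuple[int, int] = (1, 10)
    n_restarts: int = 50
    k_override: int | None = None
    standardize: bool = True
    seed: int = 0
    association_mode: str = "pearson"
    visibility_coding: str = DEFAULT_VISIBILITY_CODING
    alone_hour_window: tuple[int, int] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        if "alone_hour_window" in data and data["alone_hour_window"] is not None:
            data["alone_hour_window"] = tuple(data["alone_hour_window"])
        return cls(**data)


@dataclass
class PipelineResult:
    cleaning_report: CleaningReport
    events: pd.DataFrame
    features: pd.DataFrame
    cluster_k: int
    assignments: pd.Series
    labels: dict[int, str]
    artifacts: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(
    config: RunConfig,
    records: pd.DataFrame | None = None,
    facility: Facility | None = None,
) -> PipelineResult:
    """Run every stage and write all artifacts under ``config.output_dir``.

    ``records``/``facility`` may be passed in memory; otherwise they are read
    from the configured paths.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    if facility is None:
        facility = _stage("facility")(Facility.from_yaml)(config.facility_path)
    n_malformed = 0
    if records is None:
        records, n_malformed = _stage("read")(read_records)(config.records_path)

    # privacy scores
    def _privacy():
        assessments = assess_facility(facility, config.visibility_coding)
        tbl = privacy_table(assessments, facility)
        p = outdir / "privacy_scores.csv"
        tbl.to_csv(p)
        artifacts["privacy_scores"] = p
        return assessments
    _stage("privacy")(_privacy)()

    # cleaning
    def _clean():
        report = CleaningReport()
        cleaned = clean_records(records, window_s=config.clean_window_s, report=report)
        report.n_malformed = n_malformed
        p = outdir / "cleaning_report.json"
        p.write_text(json.dumps(report.to_dict(), indent=2))
        artifacts["cleaning_report"] = p
        return cleaned, report
    cleaned, cleaning_report = _stage("clean")(_clean)()

    # events
    def _events():
        intervals = records_to_intervals(cleaned, max_gap_s=config.max_gap_s)
        ev = detect_interactions(
            intervals, min_duration_s=config.min_duration_s,
            roster=facility.roster(), on_unknown="skip",
        )
        p = outdir / "events.csv"
        ev.to_csv(p, index=False)
        artifacts["events"] = p
        return intervals, ev
    intervals, events = _stage("interactions")(_events)()

    # networks
    def _networks():
        two = build_two_mode(intervals)
        one = project_one_mode(events, facility=facility)
        p2 = outdir / "two_mode.graphml"
        p1 = outdir / "one_mode.graphml"
        export_network(two, p2)
        export_network(one, p1)
        artifacts["two_mode"] = p2
        artifacts["one_mode"] = p1
        alone = count_alone_episodes(
            intervals, facility.roster(), min_duration_s=config.min_duration_s,
            hour_window=config.alone_hour_window,
        )
        feats = compute_features(events, facility, config.window_days, alone)
        pf = outdir / "features.csv"
        feats.to_csv(pf, float_format="%.10g")
        artifacts["features"] = pf
        grouping = {r: facility.residents[r].bedroom_type.value for r in facility.roster()}
        summary = summarize_by_group(feats, grouping)
        ps = outdir / "network_summary.csv"
        network_summary_table(summary).to_csv(ps)
        artifacts["network_summary"] = ps
        return feats
    features = _stage("network")(_networks)()

    # clustering
    def _cluster():
        matrix = build_feature_matrix(features, standardize=config.standardize)
        lo, hi = config.k_range
        hi = min(hi, len(features))
        sweep = kmeans_sweep(matrix, range(lo, hi + 1), config.n_restarts, config.seed)
        wcss = {k: m.wcss for k, m in sweep.items()}
        k = elbow_select(wcss, override=config.k_override)
        model = sweep[k]
        labels = label_clusters(model, features)
        assignments = model.assignments
        adf = pd.DataFrame(
            {"cluster": assignments, "label": assignments.map(labels)}
        )
        pa = outdir / "cluster_assignments.csv"
        adf.to_csv(pa, index_label="resident_id")
        artifacts["cluster_assignments"] = pa
        cluster_means = features.loc[assignments.index, FEATURE_COLUMNS].groupby(assignments).mean()
        flags = flag_extremes(
            cluster_means, features[FEATURE_COLUMNS].mean(), features[FEATURE_COLUMNS].std(ddof=1)
        )
        table = cluster_by_bedroom_table(assignments, facility, labels)
        pm = outdir / "cluster_means.csv"
        cluster_means_table(
            cluster_means.rename(index=labels), flags.rename(index=labels),
            table.cluster_share,
        ).to_csv(pm)
        pc = outdir / "cluster_by_bedroom.csv"
        contingency_table(table).to_csv(pc)
        pw = outdir / "wcss_by_k.json"
        pw.write_text(json.dumps({str(kk): v for kk, v in sorted(wcss.items())}, indent=2))
        artifacts["cluster_means"] = pm
        artifacts["cluster_by_bedroom"] = pc
        artifacts["wcss_by_k"] = pw
        return model, labels
    model, labels = _stage("cluster")(_cluster)()

    # associations
    def _assoc():
        tbl = association_table(
            features, facility, mode=config.association_mode,
            visibility_coding=config.visibility_coding,
        )
        p = outdir / "associations.csv"
        association_report(tbl).to_csv(p)
        pl = outdir / "associations_long.csv"
        tbl.to_frame().to_csv(pl, index=False)
        artifacts["associations"] = p
        return tbl
    _stage("associate")(_assoc)()

    # report + manifest
    def _report():
        pr = outdir / "participants.csv"
        participant_table(facility).to_csv(pr)
        artifacts["participants"] = pr
        manifest = {
            "carenet_version": __version__,
            "seed": config.seed,
            "parameters": {
                k: (list(v) if isinstance(v, tuple) else str(v) if isinstance(v, Path) else v)
                for k, v in config.__dict__.items()
            },
            "n_events": int(len(events)),
            "k": int(model.k),
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        pm = outdir / "manifest.json"
        pm.write_text(json.dumps(manifest, indent=2, default=str))
        artifacts["manifest"] = pm
    _stage("report")(_report)()

    return PipelineResult(
        cleaning_report=cleaning_report,
        events=events,
        features=features,
        cluster_k=model.k,
        assignments=model.assignments,
        labels=labels,
        artifacts=artifacts,
    )
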