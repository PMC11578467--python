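"""Stage orchestration behind the command-line interface.

Each ``run_*`` function is a plain library call: paths in, files out,
returned summary dicts.  Reports are deterministic byte-for-byte given
the same config and seeds; stage timings go to the log stream, never
into output files.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import EmptySeriesError, ValidationError
from .io import (read_landmark_stream, read_session_table, write_landmark_stream,
                 write_session_table)
from .measures import MEASURE_NAMES, MeasureSeries, compute_measure_series
from .model import (build_features, classify_cv, compare_rankings,
                    rank_importance_pca, rank_importance_trees)
from .simulate import generate_cohort
from .stats import (VideoSummary, anova_measures, anova_table, cohort_tables,
                    grouped_distributions, kruskal_wallis, summarise_video)

log = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, config: PipelineConfig, inputs: dict[str, Path],
                    counts: dict, warnings: list[str]) -> None:
    manifest = {
        "software_version": __version__,
        "config": config.to_dict(),
        "input_digests": {k: _digest(Path(p)) for k, p in inputs.items()},
        "counts": counts,
        "warnings": sorted(warnings),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_simulate(config: PipelineConfig, n_subjects: int, seed: int, out_dir: str | Path,
                 force: bool = False, **cohort_kwargs) -> dict:
    """Generate and write a synthetic cohort dataset directory."""
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"output directory {out} is not empty (use --force)")
    out.mkdir(parents=True, exist_ok=True)
    (out / "streams").mkdir(exist_ok=True)
    t0 = time.perf_counter()
    cohort = generate_cohort(n_subjects, seed=seed, lmap=config.landmark_map(),
                             **cohort_kwargs)
    for s in cohort.streams:
        write_landmark_stream(s, out / "streams" / f"{s.video_id}.json", format="json")
    write_session_table(cohort.records, out / "session.csv")
    cohort.truth.to_json(out / "truth.json")
    counts = {"n_subjects": n_subjects, "n_videos": len(cohort.streams),
              "n_session_rows": len(cohort.records)}
    _write_manifest(out, config, {"session": out / "session.csv"}, counts, [])
    log.info("simulate: %d subjects in %.2fs", n_subjects, time.perf_counter() - t0)
    return counts


def run_extract(config: PipelineConfig, dataset_dir: str | Path,
                out_csv: str | Path) -> dict:
    """Compute the tidy measures CSV for every video of a dataset directory."""
    dataset = Path(dataset_dir)
    session = dataset / "session.csv"
    if not session.exists():
        raise ValidationError(f"{dataset}: no session.csv (schema mismatch)")
    records = read_session_table(session)
    lmap = config.landmark_map()
    t0 = time.perf_counter()
    tidy_parts, dropped_videos, drop_counts = [], [], {}
    n_videos = 0
    for rec in records:
        if rec.video_id is None:
            continue
        path = dataset / "streams" / f"{rec.video_id}.json"
        if not path.exists():
            raise ValidationError(f"stream file missing for video {rec.video_id}")
        stream = read_landmark_stream(path, format="json")
        n_videos += 1
        try:
            series = compute_measure_series(stream, lmap, section=config.section,
                                            mode=config.coordinate_mode)
        except EmptySeriesError:
            dropped_videos.append(rec.video_id)
            continue
        if series.n_dropped_degenerate:
            drop_counts[rec.video_id] = series.n_dropped_degenerate
        tidy_parts.append(series.to_tidy())
    if not tidy_parts:
        raise EmptySeriesError("no video produced a non-empty measure series")
    pd.concat(tidy_parts, ignore_index=True).to_csv(out_csv, index=False)
    report = {"n_videos_read": n_videos, "n_videos_dropped": len(dropped_videos),
              "dropped_videos": sorted(dropped_videos),
              "degenerate_frame_drops": drop_counts}
    with open(Path(out_csv).with_suffix(".drops.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("extract: %d videos in %.2fs", n_videos, time.perf_counter() - t0)
    return report


def _summaries_from_tidy(config: PipelineConfig, measures_csv: str | Path,
                         session_csv: str | Path) -> list[VideoSummary]:
    tidy = pd.read_csv(measures_csv, dtype={"video_id": str})
    records = {r.video_id: r for r in read_session_table(session_csv) if r.video_id}
    orphans = sorted(set(tidy["video_id"]) - set(records))
    if orphans:
        raise ValidationError(f"measure rows reference unknown video ids: {orphans}")
    summaries = []
    for vid, grp in tidy.groupby("video_id", sort=True):
        wide = grp.pivot(index="frame_index", columns="measure", values="value")
        wide = wide[list(MEASURE_NAMES)]
        series = MeasureSeries(video_id=str(vid), section=str(grp["section"].iloc[0]),
                               frame_indices=wide.index.to_numpy(),
                               values=wide.reset_index(drop=True),
                               reference_distance=np.ones(len(wide)))
        summaries.append(summarise_video(series, records[str(vid)], ddof=config.sd_ddof))
    return summaries


def run_report(config: PipelineConfig, measures_csv: str | Path, session_csv: str | Path,
               out_dir: str | Path, label: str = "taste") -> dict:
    """Full statistics + importance report from extracted measures.

    Writes: video_sds.csv, demographics.csv, completeness.csv,
    kruskal_wallis.csv, anova_taste.csv, anova_score.csv,
    grouped_by_taste.csv, grouped_by_score.csv, importance_trees.csv,
    importance_pca.csv, ranking_agreement.json, classification.json,
    manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    records = read_session_table(session_csv)
    summaries = _summaries_from_tidy(config, measures_csv, session_csv)
    warnings: list[str] = []

    sds = pd.DataFrame([{"video_id": s.video_id, "subject_id": s.subject_id,
                         "taste": s.taste, "hedonic_score": s.hedonic_score,
                         "n_frames": s.n_frames, **s.sds.to_dict()} for s in summaries])
    sds.to_csv(out / "video_sds.csv", index=False)

    tables = cohort_tables(records)
    tables.demographics.to_csv(out / "demographics.csv", index=False)
    tables.completeness.to_csv(out / "completeness.csv", index=False)

    kw_rows = []
    for factor in ("sex", "age", "order_sequence"):
        for taste in ("control", "sour", "sweet", "bitter"):
            try:
                r = kruskal_wallis(records, factor, taste=taste)
            except ValidationError as e:
                warnings.append(f"kruskal_wallis {factor}|{taste}: {e}")
                continue
            kw_rows.append({"factor": factor, "taste": taste, "H": r.statistic,
                            "df": r.df[0], "p_value": r.p_value,
                            "significant": r.p_value < config.alpha})
    r = kruskal_wallis(records, "taste")
    kw_rows.append({"factor": "taste", "taste": "all", "H": r.statistic, "df": r.df[0],
                    "p_value": r.p_value, "significant": r.p_value < config.alpha})
    pd.DataFrame(kw_rows).to_csv(out / "kruskal_wallis.csv", index=False)

    anova_table(anova_measures(summaries, "taste")).to_csv(out / "anova_taste.csv",
                                                           index=False)
    anova_table(anova_measures(summaries, "hedonic_score")).to_csv(
        out / "anova_score.csv", index=False)
    grouped_distributions(summaries, "taste").to_csv(out / "grouped_by_taste.csv",
                                                     index=False)
    grouped_distributions(summaries, "hedonic_score").to_csv(
        out / "grouped_by_score.csv", index=False)

    matrix = build_features(summaries)
    trees = rank_importance_trees(matrix, label=label,
                                  n_seeds=config.classifier.n_importance_seeds,
                                  base_seed=config.seed)
    pca = rank_importance_pca(matrix)
    trees.to_frame().to_csv(out / "importance_trees.csv", index=False)
    pca.to_frame().to_csv(out / "importance_pca.csv", index=False)
    agreement = compare_rankings(trees, pca, k=3)
    with open(out / "ranking_agreement.json", "w") as fh:
        json.dump(agreement, fh, indent=1, sort_keys=True)
        fh.write("\n")

    n_folds = min(5, matrix.groups.nunique())
    cls = None
    if n_folds >= 2 and matrix.labels(label).nunique() >= 2:
        cls = classify_cv(matrix, label=label, folds=n_folds, seed=config.seed)
        with open(out / "classification.json", "w") as fh:
            json.dump({"label": cls.label, "accuracy": cls.accuracy,
                       "chance_level": cls.chance_level, "n_folds": cls.n_folds,
                       "per_class_accuracy": cls.per_class_accuracy.to_dict(),
                       "confusion": cls.confusion.to_dict()}, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        warnings.append("classification skipped: too few subjects or classes")

    counts = {"n_records": len(records), "n_videos_summarised": len(summaries),
              "n_feature_rows": len(matrix.X), "n_feature_rows_dropped": matrix.n_dropped,
              "n_kw_tests": len(kw_rows), "n_anova_tests": 2 * len(MEASURE_NAMES)}
    _write_manifest(out, config, {"measures": Path(measures_csv),
                                  "session": Path(session_csv)}, counts, warnings)
    log.info("report: %d videos in %.2fs", len(summaries), time.perf_counter() - t0)
    return {"counts": counts, "agreement": agreement,
            "top_measure_trees": trees.ranking[0],
            "accuracy": None if cls is None else cls.accuracy}
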