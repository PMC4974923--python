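"""End-to-end orchestration: simulate → filter → segment → features →
select → classify → report.

Every stage writes/reads the documented plain-text formats so stages can
be inspected and rerun independently; a run's effective configuration is
always serialized next to its outputs, and identical (config, seed)
reproduce identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import classify, io_model, selection, synthetic
from .errors import EmogaitError
from .features import FEATURE_NAMES, extract_features
from .io_model import TASKS, TriaxialRecording
from .preprocess import FilterConfig, SegmentationConfig, filter_recording, segment

logger = logging.getLogger(__name__)

_META_COLUMNS = ["subject_id", "site", "emotion", "window_index"]


def build_feature_table(
    recordings: Sequence[TriaxialRecording],
    filter_cfg: FilterConfig,
    seg_cfg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Filter, segment and featurize a collection of recordings.

    Returns one row per segment: provenance columns plus the 114 named
    feature columns.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    rows = []
    for rec in recordings:
        filtered = filter_recording(rec, filter_cfg)
        for seg in segment(filtered, seg_cfg):
            fv = extract_features(seg)
            row = {
                "subject_id": fv.subject_id,
                "site": fv.site,
                "emotion": fv.label,
                "window_index": fv.window_index,
            }
            row.update(zip(fv.names, fv.values))
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=_META_COLUMNS + list(FEATURE_NAMES))
    return pd.DataFrame(rows, columns=_META_COLUMNS + list(FEATURE_NAMES))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end run needs; fully serializable."""

    input_dir: str | None = None  # read recordings from here, unless simulating
    simulate: bool = True
    n_subjects: int = 40
    effect_scale: float = 1.0
    filter_widths: tuple[int, ...] = (3, 5)
    windowsize: int = 128
    step: int = 64
    selection_threshold: float = 0.95
    loading_cutoff: float = 0.71
    paper_mode: bool = False
    cv_folds: int = 10
    seed: int = 0
    tasks: tuple[str, ...] = tuple(TASKS)
    sites: tuple[str, ...] = io_model.SITES
    algorithms: tuple[str, ...] = classify.ALGORITHMS

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_recordings(config: PipelineConfig) -> list[TriaxialRecording]:
    if config.simulate:
        cohort = synthetic.CohortConfig(
            n_subjects=config.n_subjects,
            sites=tuple(config.sites),
            effect_scale=config.effect_scale,
            seed=config.seed,
        )
        return synthetic.generate_cohort(cohort)
    if not config.input_dir:
        raise EmogaitError("no input_dir given and simulate is off")
    path = Path(config.input_dir)
    if path.is_file():
        files = [path]
    else:
        files = sorted(path.glob("*.csv"))
    if not files:
        raise EmogaitError(f"no recording files found under {path}")
    recordings: list[TriaxialRecording] = []
    for f in files:
        recordings.extend(io_model.read_recordings(f))
    return recordings


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full analysis and write all artifacts under ``out_dir``.

    Writes: the (possibly simulated) recordings, one feature matrix per
    filter width, a selection report per (w, site), the grid results
    table, formatted per-task tables, and the effective config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")

    recordings = _load_recordings(config)
    if config.simulate:
        io_model.write_recordings(recordings, out / "recordings.csv")

    seg_cfg = SegmentationConfig(windowsize=config.windowsize, step=config.step)
    tables: dict[int, pd.DataFrame] = {}
    for w in config.filter_widths:
        table = build_feature_table(recordings, FilterConfig(w), seg_cfg)
        table.to_csv(out / f"features_w{w}.csv", index=False)
        tables[w] = table

    # whole-dataset selection report per (w, site) — the per-fold selection
    # inside cross-validation is separate unless paper_mode is set
    report: dict[str, dict] = {}
    for w, table in tables.items():
        for site in config.sites:
            sub = table[table["site"] == site]
            if len(sub) < 2:
                continue
            model = selection.fit_select(sub[list(FEATURE_NAMES)], config.selection_threshold)
            loadings = selection.loading_report(model, config.loading_cutoff)
            report[f"w{w}_{site}"] = {
                "n_retained": model.n_retained,
                "cumulative_share": model.cumulative_share,
                "explained_variance_shares": [
                    float(v) for v in model.explained_variance_shares[: model.n_retained]
                ],
                "loadings": {str(k): v for k, v in loadings.items()},
            }
    (out / "selection_report.json").write_text(json.dumps(report, indent=2) + "\n")

    grid = classify.run_grid(
        tables,
        tasks=config.tasks,
        sites=config.sites,
        algorithms=config.algorithms,
        k=config.cv_folds,
        seed=config.seed,
        selection_cfg=classify.SelectionConfig(
            threshold=config.selection_threshold,
            loading_cutoff=config.loading_cutoff,
            paper_mode=config.paper_mode,
        ),
    )
    grid.to_csv(out / "grid_results.csv", index=False)
    rendered = "\n\n".join(classify.format_grid(grid, task) for task in config.tasks)
    (out / "grid_results.txt").write_text(rendered + "\n")
    logger.info("pipeline finished: %d grid cells -> %s", len(grid), out)
    return out
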