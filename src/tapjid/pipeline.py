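"""End-to-end contrast pipeline.

Orchestrates the full analysis: segmentation of a raw tap stream into
behavioural days, one JID per day, grouping of days into the pre-tapering /
tapering / post-tapering periods, the two medication-transition
cluster-permutation tests, and the descriptive convulsion-day-vs-baseline
contrast.  Driven either by raw tap files plus a design table or by the
synthetic generator (``simulate: true``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import ClusterTestResult, permutation_test, result_to_dict, write_result
from .errors import DesignError, EmptyInputError
from .io import DayRecord, TapStream, read_taps, write_jid, write_taps
from .jid import (
    JID,
    DifferenceMap,
    JIDGrid,
    average_jid,
    compute_jid,
    jid_difference,
    make_pairs,
)
from .segmentation import SegmentationParams, detect_rise_times, segmentation_report, split_days
from .synthetic import SynthConfig, config_from_dict, generate_study, summarize_study

logger = logging.getLogger(__name__)

PERIODS = ("pre", "taper", "post")


@dataclass
class StudyDesign:
    """Mapping of behavioural days to study periods and the seizure day."""

    period_map: dict[int, str]
    seizure_day: int | None = None
    baseline_days: int = 3
    exclusion_flags: set[int] = field(default_factory=set)
    #: keep the convulsion day inside its period for the transition tests
    #: (the monitored tapering period contained the convulsive event);
    #: set False to exclude it from group statistics.
    include_seizure_in_groups: bool = True

    def __post_init__(self) -> None:
        bad = set(self.period_map.values()) - set(PERIODS)
        if bad:
            raise DesignError(f"unknown period label(s): {sorted(bad)}")
        if self.seizure_day is not None and self.seizure_day not in self.period_map:
            raise DesignError(f"seizure day {self.seizure_day} not in period map")
        if self.baseline_days < 1:
            raise DesignError("baseline_days must be >= 1")

    def period_days(self, period: str) -> list[int]:
        """Non-excluded day ids of one period, in order."""
        days = [
            d for d, p in sorted(self.period_map.items())
            if p == period and d not in self.exclusion_flags
        ]
        if not self.include_seizure_in_groups and self.seizure_day is not None:
            days = [d for d in days if d != self.seizure_day]
        return days


def compute_daily_jids(
    records: list[DayRecord],
    grid: JIDGrid | None = None,
    exclude_flagged: bool = True,
) -> tuple[dict[int, JID], set[int]]:
    """One JID per day record; returns (jids, excluded day ids).

    Days flagged low-count/partial (when ``exclude_flagged``) or with fewer
    than two ITIs are excluded and reported rather than silently dropped.
    """
    if grid is None:
        grid = JIDGrid()
    jids: dict[int, JID] = {}
    excluded: set[int] = set()
    for rec in records:
        if exclude_flagged and rec.flags:
            excluded.add(rec.day_id)
            continue
        pairs = make_pairs(rec.itis)
        if pairs.shape[0] == 0:
            logger.warning("day %d has < 2 ITIs; excluded", rec.day_id)
            excluded.add(rec.day_id)
            continue
        jids[rec.day_id] = compute_jid(pairs, grid)
    return jids, excluded


@dataclass
class TransitionResults:
    """The two medication-transition tests with period summaries."""

    pre_vs_taper: ClusterTestResult
    taper_vs_post: ClusterTestResult
    period_averages: dict[str, JID]
    difference_maps: dict[str, DifferenceMap]


def run_transition_tests(
    daily_jids: dict[int, JID],
    design: StudyDesign,
    B: int = 1000,
    seed: int = 0,
    **test_kwargs,
) -> TransitionResults:
    """Pre-vs-taper and taper-vs-post max-cluster-size permutation tests.

    Also returns the period-average JIDs and their signed difference maps
    (taper minus pre, post minus taper).
    """
    groups: dict[str, list[JID]] = {}
    for period in PERIODS:
        days = [d for d in design.period_days(period) if d in daily_jids]
        if len(days) < 2:
            raise DesignError(
                f"period {period!r} has {len(days)} usable day(s); need >= 2"
            )
        if len(days) < 5:
            logger.warning("period %r has only %d days", period, len(days))
        groups[period] = [daily_jids[d] for d in days]

    averages = {p: average_jid(groups[p]) for p in PERIODS}
    diffs = {
        "taper_minus_pre": jid_difference(
            averages["taper"], averages["pre"], label="taper - pre"
        ),
        "post_minus_taper": jid_difference(
            averages["post"], averages["taper"], label="post - taper"
        ),
    }
    res1 = permutation_test(groups["pre"], groups["taper"], B=B, seed=seed, **test_kwargs)
    res2 = permutation_test(groups["taper"], groups["post"], B=B, seed=seed + 1, **test_kwargs)
    return TransitionResults(
        pre_vs_taper=res1,
        taper_vs_post=res2,
        period_averages=averages,
        difference_maps=diffs,
    )


@dataclass
class SeizureContrast:
    """Convulsion day vs the average of the preceding baseline days."""

    difference: DifferenceMap
    seizure_day: int
    baseline_day_ids: list[int]
    quadrant_mass: dict[str, float]


def run_seizure_contrast(
    daily_jids: dict[int, JID], design: StudyDesign
) -> SeizureContrast:
    """Descriptive single-day contrast: JID(seizure day) - mean(previous days).

    No hypothesis test is attached — a single day admits no day-level
    permutation — matching the source analysis, which tests only the
    medication transitions.
    """
    if design.seizure_day is None:
        raise DesignError("design has no seizure day")
    if design.seizure_day not in daily_jids:
        raise DesignError(f"no JID for seizure day {design.seizure_day}")
    preceding = sorted(
        d for d in daily_jids if d < design.seizure_day and d not in design.exclusion_flags
    )
    baseline_ids = preceding[-design.baseline_days:]
    if len(baseline_ids) < design.baseline_days:
        raise DesignError(
            f"need {design.baseline_days} baseline day(s) before day "
            f"{design.seizure_day}, found {len(baseline_ids)}"
        )
    baseline = average_jid([daily_jids[d] for d in baseline_ids])
    diff = jid_difference(
        daily_jids[design.seizure_day], baseline, label="seizure - baseline"
    )
    return SeizureContrast(
        difference=diff,
        seizure_day=design.seizure_day,
        baseline_day_ids=baseline_ids,
        quadrant_mass=diff.quadrant_mass(),
    )


# ---------------------------------------------------------------------------
# full pipeline

def _grid_from_config(cfg: dict) -> JIDGrid:
    return JIDGrid(**cfg.get("grid", {}))


def _segparams_from_config(cfg: dict) -> SegmentationParams:
    return SegmentationParams(**cfg.get("segmentation", {}))


def design_from_table(df: pd.DataFrame, baseline_days: int = 3,
                      include_seizure_in_groups: bool = True) -> StudyDesign:
    """Build a StudyDesign from a (day_id, label, seizure) table."""
    period_map = dict(zip(df["day_id"].astype(int), df["label"]))
    seizure_rows = df.loc[df.get("seizure", pd.Series(False, index=df.index)).astype(bool)]
    if len(seizure_rows) > 1:
        raise DesignError("design table flags more than one seizure day")
    seizure_day = int(seizure_rows["day_id"].iloc[0]) if len(seizure_rows) else None
    return StudyDesign(
        period_map=period_map,
        seizure_day=seizure_day,
        baseline_days=baseline_days,
        include_seizure_in_groups=include_seizure_in_groups,
    )


@dataclass
class RunResult:
    """In-memory bundle of one full pipeline run."""

    daily_jids: dict[int, JID]
    design: StudyDesign
    transitions: TransitionResults
    seizure: SeizureContrast | None
    segmentation: pd.DataFrame
    out_dir: Path | None


def run_full_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> RunResult:
    """Execute the whole analysis from a config mapping or YAML path.

    The config either sets ``simulate: true`` with a ``synth`` block
    (generator parameters) or gives ``taps`` (CSV path) and ``design``
    (day_id/label/seizure table path).  Results are written under
    ``out_dir`` when given: per-day JIDs, the segmentation report, both
    transition test results, the seizure contrast, and a run manifest.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    t_start = time.perf_counter()
    timings: dict[str, float] = {}

    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "tapjid_run"))
    grid = _grid_from_config(cfg)
    seg_params = _segparams_from_config(cfg)
    B = int(cfg.get("B", 1000))
    seed = int(cfg.get("seed", 0))
    baseline_days = int(cfg.get("baseline_days", 3))
    include_seizure = not bool(cfg.get("exclude_seizure_from_taper", False))
    test_kwargs = dict(cfg.get("test", {}))

    if cfg.get("simulate", False):
        synth_cfg = config_from_dict({"seed": seed, **cfg.get("synth", {})})
        study = generate_study(synth_cfg)
        stream = study.to_stream()
        design_df = summarize_study(study).table[["day_id", "label", "seizure"]]
    else:
        taps_path = Path(cfg["taps"])
        design_path = Path(cfg["design"])
        for p in (taps_path, design_path):
            if not p.exists():
                raise FileNotFoundError(f"pipeline input not found: {p}")
        stream = read_taps(taps_path)
        design_df = pd.read_csv(design_path)
    timings["ingest"] = time.perf_counter() - t_start

    t0 = time.perf_counter()
    rise_times = detect_rise_times(stream, seg_params)
    records = split_days(stream, rise_times, seg_params)
    seg_table = segmentation_report(records)
    if len(records) != len(design_df):
        raise DesignError(
            f"segmentation produced {len(records)} day(s) but the design "
            f"table lists {len(design_df)}; align labels to days first"
        )
    timings["segmentation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    daily_jids, excluded = compute_daily_jids(records, grid)
    timings["jid_estimation"] = time.perf_counter() - t0

    design = design_from_table(
        design_df, baseline_days=baseline_days,
        include_seizure_in_groups=include_seizure,
    )
    design.exclusion_flags |= excluded

    t0 = time.perf_counter()
    transitions = run_transition_tests(daily_jids, design, B=B, seed=seed, **test_kwargs)
    timings["transition_tests"] = time.perf_counter() - t0

    seizure = None
    if design.seizure_day is not None and design.seizure_day in daily_jids:
        t0 = time.perf_counter()
        seizure = run_seizure_contrast(daily_jids, design)
        timings["seizure_contrast"] = time.perf_counter() - t0

    out.mkdir(parents=True, exist_ok=True)
    if cfg.get("simulate", False):
        write_taps(stream, out / "taps.csv")
        design_df.to_csv(out / "design.csv", index=False)
    seg_table.to_csv(out / "segmentation.tsv", sep="\t", index=False)
    jid_dir = out / "jids"
    for day_id, jid in daily_jids.items():
        write_jid(jid, jid_dir / f"day_{day_id:04d}.jid")
    write_result(transitions.pre_vs_taper, out / "pre_vs_taper.json")
    write_result(transitions.taper_vs_post, out / "taper_vs_post.json")
    if seizure is not None:
        with open(out / "seizure_contrast.json", "w") as fh:
            json.dump(
                {
                    "seizure_day": seizure.seizure_day,
                    "baseline_day_ids": seizure.baseline_day_ids,
                    "quadrant_mass": seizure.quadrant_mass,
                    "difference": seizure.difference.matrix.tolist(),
                },
                fh,
                indent=1,
            )
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "B": B,
        "n_days": len(records),
        "n_excluded": len(design.exclusion_flags),
        "excluded_days": sorted(design.exclusion_flags),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "timings.log", "w") as fh:
        for stage, dt in timings.items():
            fh.write(f"{stage}\t{dt:.3f}s\n")
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t_start)
    return RunResult(
        daily_jids=daily_jids,
        design=design,
        transitions=transitions,
        seizure=seizure,
        segmentation=seg_table,
        out_dir=out,
    )
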