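"""End-to-end orchestration: read/validate -> segment -> aggregate -> models.

`analyze` is the in-memory pipeline over (events, windows, metadata);
`run_pipeline` wraps it with file I/O, optional simulation of the inputs,
logging, and CSV/JSON outputs in a run directory.  All randomness flows
from the config seed, so a rerun with the same config reproduces the same
numeric outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import aggregation, io, models, segmentation, solar, synthetic
from .aggregation import FilterThresholds
from .io import FEMALE, MALE

__all__ = ["PipelineConfig", "AnalysisResults", "analyze", "run_pipeline"]

log = logging.getLogger("lapwing")


@dataclass
class PipelineConfig:
    """Run configuration; defaults reproduce the study's filter settings."""

    outdir: str = "run"
    events: Optional[str] = None
    windows: Optional[str] = None
    metadata: Optional[str] = None
    simulate: Optional[synthetic.SimulationConfig] = None
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    run_models: bool = True
    n_draws: int = 5000
    n_bootstrap: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and not (self.events and self.windows and self.metadata):
            raise ValueError("config needs input paths or a simulate block")
        if self.n_draws < 2 or self.n_bootstrap < 2:
            raise ValueError("n_draws and n_bootstrap must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filters" in raw:
            raw["filters"] = FilterThresholds(**raw["filters"])
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("season_start", "season_end"):
                if key in sim and isinstance(sim[key], str):
                    sim[key] = dt.date.fromisoformat(sim[key])
            for key in ("monitoring_days_range", "male_share_beta",
                        "attendance_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = synthetic.SimulationConfig(**sim)
        return cls(**raw)


@dataclass
class AnalysisResults:
    """All pipeline tables for a study."""

    hourly: pd.DataFrame
    daily: pd.DataFrame
    nests: pd.DataFrame
    parents: pd.DataFrame
    median_bouts: pd.DataFrame
    night_bouts: pd.DataFrame
    bouts: pd.DataFrame
    gaps: pd.DataFrame
    nights: pd.DataFrame
    segmentations: dict = field(default_factory=dict)  # nest_id -> (kept, excl)

    def model_tables(self) -> dict:
        return {
            "nests": self.nests,
            "parents": self.parents,
            "daily": self.daily,
            "hourly": self.hourly,
            "bouts": self.bouts[self.bouts["complete"] & ~self.bouts["tainted"]],
            "night_bouts": self.night_bouts,
            "median_bouts": self.median_bouts,
            "gaps": self.gaps[self.gaps["complete"] & (self.gaps["seconds"] > 0)],
        }


def _bout_frame(kept: segmentation.Segmentation, meta: io.NestMetadata) -> pd.DataFrame:
    rows = []
    ordered = sorted(kept.bouts, key=lambda b: b.start)
    prev_seconds = np.nan
    for b in ordered:
        loc = b.start.astimezone(meta.tz)
        rows.append(
            {
                "nest_id": b.nest_id,
                "sex": b.sex,
                "start": b.start.isoformat(),
                "end": b.end.isoformat(),
                "seconds": b.seconds,
                "attended_seconds": b.attended_seconds,
                "n_recesses": len(b.recesses),
                "complete": b.complete,
                "tainted": b.tainted,
                "time_h": loc.hour + loc.minute / 60.0 + loc.second / 3600.0,
                "day_of_incubation": max(0, (loc.date() - meta.incubation_start).days),
                "season_start_day": meta.season_start_day,
                "day_in_season": int(loc.timetuple().tm_yday),
                "prev_seconds": float(prev_seconds),
            }
        )
        prev_seconds = b.seconds
    return pd.DataFrame(rows)


def _gap_frame(kept: segmentation.Segmentation, meta: io.NestMetadata) -> pd.DataFrame:
    rows = []
    for g in sorted(kept.gaps, key=lambda g: g.start):
        loc = g.start.astimezone(meta.tz)
        rows.append(
            {
                "nest_id": g.nest_id,
                "start": g.start.isoformat(),
                "end": g.end.isoformat(),
                "seconds": g.seconds,
                "precedes_sex": g.precedes_sex,
                "complete": g.complete,
                "time_h": loc.hour + loc.minute / 60.0 + loc.second / 3600.0,
                "day_of_incubation": max(0, (loc.date() - meta.incubation_start).days),
                "season_start_day": meta.season_start_day,
                "day_in_season": int(loc.timetuple().tm_yday),
            }
        )
    return pd.DataFrame(rows)


def analyze(
    events,
    windows,
    metadata,
    filters: FilterThresholds = aggregation.DEFAULT_FILTERS,
) -> AnalysisResults:
    """Validate, segment, and aggregate a whole study.

    Raises on fatal validation errors; returns all tables otherwise.
    """
    report = io.validate_events(events, windows)
    if not report.ok:
        heads = "; ".join(v.message for v in report.fatal[:5])
        raise io.ValidationError(
            f"{len(report.fatal)} fatal validation errors (first: {heads})"
        )
    meta_by_nest = {m.nest_id: m for m in metadata}
    ev_by_nest: dict[str, list] = {}
    for ev in events:
        ev_by_nest.setdefault(ev.nest_id, []).append(ev)
    win_by_nest: dict[str, list] = {}
    for w in windows:
        win_by_nest.setdefault(w.nest_id, []).append(w)

    hourly, daily, nests, med, night, bframes, gframes, nightrows = (
        [], [], [], [], [], [], [], []
    )
    segs: dict = {}
    for nest_id in sorted(win_by_nest):
        meta = meta_by_nest.get(nest_id)
        if meta is None:
            raise io.ValidationError(f"nest {nest_id} has windows but no metadata")
        nest_windows = sorted(win_by_nest[nest_id])
        nest_events = ev_by_nest.get(nest_id, [])
        seg = segmentation.segment_nest(nest_events, nest_windows)
        kept, excluded = segmentation.apply_quality_exclusions(seg)
        segs[nest_id] = (kept, excluded, nest_windows)

        h = aggregation.hourly_table(kept, excluded, nest_windows, meta.tz, filters)
        d = aggregation.daily_table(kept, excluded, nest_windows, meta, filters)
        s = aggregation.nest_summary(kept, excluded, nest_windows, meta, d, filters)
        span_dates = sorted({r["date"] for r in d.to_dict("records")}) if len(d) else []
        nb = aggregation.longest_night_bouts(kept, meta, span_dates, filters)
        hourly.append(h)
        daily.append(d)
        nests.append(s)
        night.append(nb)
        bframes.append(_bout_frame(kept, meta))
        gframes.append(_gap_frame(kept, meta))

        ctx = solar.SolarContext(meta.latitude, meta.longitude, meta.utc_offset)
        for date in span_dates:
            n = solar.night_for_evening(ctx, date)
            if n is not None:
                nightrows.append(
                    {
                        "nest_id": nest_id,
                        "date": date.isoformat(),
                        "night_start": n.start.isoformat(),
                        "night_end": n.end.isoformat(),
                        "night_length_s": n.length,
                    }
                )

    nests_df = pd.DataFrame(nests)
    parents_rows, med_rows = [], []
    for s in nests:
        if not s["included"] or s["uniparental"]:
            continue
        for sex, att, resp, medb in (
            (FEMALE, s["female_attendance"], s["female_responsibility"],
             s["median_bout_female_s"]),
            (MALE, s["male_attendance"], s["male_responsibility"],
             s["median_bout_male_s"]),
        ):
            parents_rows.append(
                {
                    "nest_id": s["nest_id"],
                    "sex": sex,
                    "attendance": att,
                    "responsibility": resp,
                    "n_days_included": s["n_days_included"],
                }
            )
            med_rows.append(
                {
                    "nest_id": s["nest_id"],
                    "sex": sex,
                    "attendance": att,
                    "median_bout_s": medb,
                    "n_days_included": s["n_days_included"],
                }
            )

    def cat(frames):
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    return AnalysisResults(
        hourly=cat(hourly),
        daily=cat(daily),
        nests=nests_df,
        parents=pd.DataFrame(parents_rows),
        median_bouts=pd.DataFrame(med_rows),
        night_bouts=cat(night),
        bouts=cat(bframes),
        gaps=cat(gframes),
        nights=pd.DataFrame(nightrows),
        segmentations=segs,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline into ``config.outdir``; returns the path."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s",
                          datefmt="%Y-%m-%dT%H:%M:%S")
    )
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if config.simulate is not None:
            log.info("simulating study: %d nests, seed %d",
                     config.simulate.n_nests, config.simulate.seed)
            study = synthetic.simulate_study(config.simulate)
            indir = outdir / "inputs"
            study.write(indir)
            events, windows, metadata = study.events, study.windows, study.metadata
        else:
            events = io.read_events(config.events)
            windows = io.read_windows(config.windows)
            metadata = io.read_metadata(config.metadata)
        log.info("inputs: %d events, %d windows, %d nests",
                 len(events), len(windows), len(metadata))

        results = analyze(events, windows, metadata, config.filters)
        log.info(
            "segmented %d bouts, %d gaps; %d/%d nests pass the %d-day filter",
            len(results.bouts), len(results.gaps),
            int(results.nests["included"].sum()) if len(results.nests) else 0,
            len(results.nests), config.filters.min_days,
        )

        results.hourly.to_csv(outdir / "attendance_hourly.csv", index=False)
        results.daily.to_csv(outdir / "attendance_daily.csv", index=False)
        results.nests.to_csv(outdir / "nest_summary.csv", index=False)
        results.night_bouts.to_csv(outdir / "night_bouts.csv", index=False)
        results.bouts.to_csv(outdir / "bouts.csv", index=False)
        results.gaps.to_csv(outdir / "gaps.csv", index=False)
        results.nights.to_csv(outdir / "nights.csv", index=False)

        estimates: dict = {}
        if config.run_models:
            suite = models.run_model_suite(
                results.model_tables(), n_draws=config.n_draws, seed=config.seed
            )
            report = models.suite_report(suite)
            report.to_csv(outdir / "models_report.csv", index=False)
            for name, res in suite.items():
                if "error" in res:
                    log.warning("model %s failed: %s", name, res["error"])
                else:
                    log.info("model %s: n=%d%s", name, res["fit"].n_obs,
                             " (fallback)" if res["fit"].fallback_used else "")
            try:
                comp = models.compensation(
                    results.nests, n_draws=config.n_draws, seed=config.seed
                )
                estimates["compensation"] = dataclasses.asdict(comp)
            except ValueError as exc:
                log.warning("compensation not estimable: %s", exc)
            for sex in (FEMALE, MALE):
                try:
                    daily = results.daily[results.daily["included"]]
                    if sex == MALE and len(results.nests):
                        biparental = set(
                            results.nests.loc[~results.nests["uniparental"], "nest_id"]
                        )
                        daily = daily[daily["nest_id"].isin(biparental)]
                    rep = models.repeatability(
                        daily, sex, n_bootstrap=config.n_bootstrap, seed=config.seed
                    )
                    estimates[f"repeatability_{sex}"] = dataclasses.asdict(rep)
                except ValueError as exc:
                    log.warning("repeatability (%s) not estimable: %s", sex, exc)
            with open(outdir / "estimates.json", "w") as fh:
                json.dump(estimates, fh, indent=1, sort_keys=True)
        log.info("pipeline complete: %s", outdir)
        return outdir
    finally:
        log.removeHandler(handler)
        handler.close()
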