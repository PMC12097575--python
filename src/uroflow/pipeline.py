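"""End-to-end orchestration: simulate → compensate/gate → summarize → stats → report.

Each stage consumes and produces the CSV interfaces of the other modules,
so chaining the stages on disk is identical to :func:`run_pipeline`.
Every output directory receives a ``run_log.json`` with the package
version and a hash of the effective configuration — the thresholds carry
all the scientific weight, so they must be auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compensation import SpilloverMatrix, apply_compensation, estimate_spillover
from .errors import FormatError, ValidationError
from .gating import CRYSTAL_METHODS, GateConfig, classify_sample
from .io import (
    EventTable,
    SampleRecord,
    manifest_frame,
    read_event_table,
    read_manifest,
    write_event_table,
    write_manifest,
)
from .quantify import (
    daily_load,
    merge_replicates,
    read_summaries,
    summaries_to_frame,
    summarize_sample,
    write_summaries,
)
from .stats import cohort_analysis
from .synthdata import SyntheticCohortSpec, generate_cohort, generate_controls

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Single-file configuration of a full run."""

    out_dir: str = "uroflow_out"
    input_dir: str | None = None  # None -> simulate a cohort
    cohort: SyntheticCohortSpec = dataclasses.field(default_factory=SyntheticCohortSpec)
    gates: GateConfig = dataclasses.field(default_factory=GateConfig)
    daily_volume_mL: float = 1400.0
    include_outliers: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.daily_volume_mL <= 0:
            raise ValidationError("daily_volume_mL must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cohort = SyntheticCohortSpec(**payload.pop("cohort", {}))
        gates = GateConfig(**payload.pop("gates", {}))
        return cls(cohort=cohort, gates=gates, **payload)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_run_log(out_dir: Path, config_hash: str, stage: str, extra: dict | None = None) -> None:
    log_path = out_dir / "run_log.json"
    entries = []
    if log_path.exists():
        entries = json.loads(log_path.read_text())
    entries.append(
        {"stage": stage, "version": __version__, "config_hash": config_hash, **(extra or {})}
    )
    log_path.write_text(json.dumps(entries, indent=1))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def simulate_stage(spec: SyntheticCohortSpec, out_dir: str | Path) -> Path:
    """Generate a cohort and write manifest, truth, controls and events."""
    out_dir = Path(out_dir)
    (out_dir / "events").mkdir(parents=True, exist_ok=True)
    (out_dir / "controls").mkdir(exist_ok=True)
    cohort = generate_cohort(spec)
    write_manifest(cohort.records, out_dir / "manifest.csv")
    cohort.truth.to_csv(out_dir / "truth.csv", index=False)
    cohort.spillover.to_csv(out_dir / "spillover_true.csv")
    for ch, table in generate_controls(spec.seed, cohort.spillover).items():
        write_event_table(table, out_dir / "controls" / f"{ch}.csv")
    for (sample_id, rep), table in cohort.tables.items():
        write_event_table(table, out_dir / "events" / f"{sample_id}-r{rep}.csv")
    return out_dir


def _load_spillover(in_dir: Path) -> SpilloverMatrix:
    controls_dir = in_dir / "controls"
    if controls_dir.is_dir() and any(controls_dir.glob("*.csv")):
        controls = {
            p.stem: read_event_table(p)
            for p in sorted(controls_dir.glob("*.csv"))
            if not p.name.endswith(".volume")
        }
        return estimate_spillover(controls)
    matrix_path = in_dir / "spillover_true.csv"
    if matrix_path.exists():
        return SpilloverMatrix.from_csv(matrix_path)
    logger.warning("no controls or spillover matrix found; assuming identity")
    return SpilloverMatrix.identity()


def gate_stage(
    in_dir: str | Path, out_dir: str | Path, gates: GateConfig | None = None
) -> Path:
    """Compensate and classify every event table under ``in_dir/events``.

    Writes per-sample label tables to ``out_dir/labels`` plus a
    ``gate_counts.csv`` of per-class counts; the gate thresholds used are
    written back out as ``gates.yaml``.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    events_dir = in_dir / "events"
    if not events_dir.is_dir():
        raise FormatError(f"no events directory under {in_dir}")
    gates = gates or GateConfig()
    spillover = _load_spillover(in_dir)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    spillover.to_csv(out_dir / "spillover_estimated.csv")
    gates.to_yaml(out_dir / "gates.yaml")
    count_rows = []
    event_files = sorted(p for p in events_dir.glob("*.csv") if not p.name.endswith(".volume"))
    if not event_files:
        raise FormatError(f"no event tables under {events_dir}")
    for path in event_files:
        table = read_event_table(path)
        result = classify_sample(apply_compensation(table, spillover), gates)
        key = path.stem  # "<sample_id>-r<rep>"
        result.labels.to_csv(out_dir / "labels" / f"{key}.csv", index=False)
        row = {"key": key, "n_beads": result.n_beads,
               "n_size_dropped": result.n_size_dropped, **result.counts}
        row.update({f"crystals_{m}": result.crystal_counts[m] for m in CRYSTAL_METHODS})
        count_rows.append(row)
    pd.DataFrame(count_rows).to_csv(out_dir / "gate_counts.csv", index=False)
    return out_dir


def _load_gating_result(gated_dir: Path, key: str, gate_counts: pd.DataFrame):
    """Rebuild a GatingResult from the gate stage's on-disk outputs."""
    from .gating import GatingResult, PRIMARY_CLASSES

    labels = pd.read_csv(gated_dir / "labels" / f"{key}.csv")
    if key not in gate_counts.index:
        raise ValidationError(f"no gate counts recorded for {key}")
    row = gate_counts.loc[key]
    counts = {c: int(row[c]) for c in PRIMARY_CLASSES}
    crystal_counts = {m: int(row[f"crystals_{m}"]) for m in CRYSTAL_METHODS}
    return GatingResult(
        labels=labels,
        counts=counts,
        crystal_counts=crystal_counts,
        n_beads=int(row["n_beads"]),
        n_size_dropped=int(row["n_size_dropped"]),
    )


def summarize_stage(
    in_dir: str | Path, gated_dir: str | Path, out_dir: str | Path
) -> Path:
    """Per-sample summaries from gated events; replicates merged.

    Writes ``summaries_raw.csv`` (one row per measurement) and
    ``summaries.csv`` (one row per sample, replicate-merged).
    """
    in_dir, gated_dir, out_dir = Path(in_dir), Path(gated_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = {r.sample_id: r for r in read_manifest(in_dir / "manifest.csv")}
    if not records:
        raise ValidationError("empty cohort: manifest has no samples")
    gate_counts = pd.read_csv(gated_dir / "gate_counts.csv").set_index("key")
    per_sample: dict[str, dict[int, object]] = {}
    raw = []
    for path in sorted((in_dir / "events").glob("*.csv")):
        if path.name.endswith(".volume"):
            continue
        stem = path.stem
        sample_id, _, rep_tag = stem.rpartition("-r")
        rep = int(rep_tag)
        if sample_id not in records:
            logger.warning("event table %s has no manifest row; skipped", stem)
            continue
        table = read_event_table(path)
        result = _load_gating_result(gated_dir, stem, gate_counts)
        summary = summarize_sample(result, table, records[sample_id])
        per_sample.setdefault(sample_id, {})[rep] = summary
        raw.append(summary)
    merged = []
    for sample_id, reps in per_sample.items():
        merged.append(merge_replicates(reps[1], reps.get(2)))
    write_summaries(raw, out_dir / "summaries_raw.csv")
    write_summaries(merged, out_dir / "summaries.csv")
    return out_dir


def stats_stage(
    in_dir: str | Path, summaries_dir: str | Path, out_dir: str | Path,
    include_outliers: bool = False,
) -> Path:
    """Cohort group summaries and hypothesis tests from merged summaries."""
    in_dir, summaries_dir, out_dir = Path(in_dir), Path(summaries_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest_frame(read_manifest(in_dir / "manifest.csv"))
    summaries = read_summaries(summaries_dir / "summaries.csv")
    if summaries.empty:
        raise ValidationError("empty cohort: no sample summaries")
    analysis = cohort_analysis(summaries, manifest)
    analysis.group_summaries.to_csv(out_dir / "group_summaries.csv", index=False)
    analysis.test_results.to_csv(out_dir / "test_results.csv", index=False)
    analysis.excluded_outliers.to_csv(out_dir / "outlier_samples.csv", index=False)
    return out_dir


def report_stage(
    in_dir: str | Path, summaries_dir: str | Path, stats_dir: str | Path,
    out_dir: str | Path, daily_volume_mL: float = 1400.0,
) -> Path:
    """Cohort-level report: headline quantities and class proportions.

    ``proportions.csv`` holds the mean share of each particle class
    overall and within every factor level (the proportional-distribution
    data behind the usual pie/bar panels).
    """
    in_dir, summaries_dir, stats_dir, out_dir = map(
        Path, (in_dir, summaries_dir, stats_dir, out_dir)
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest_frame(read_manifest(in_dir / "manifest.csv"))
    summaries = read_summaries(summaries_dir / "summaries.csv")
    if summaries.empty:
        raise ValidationError("empty cohort: nothing to report")
    merged = summaries.merge(manifest, on="sample_id", how="left")
    base = merged.loc[~merged["outlier_flag"].astype(bool)]

    from .gating import PRIMARY_CLASSES  # local import avoids cycle at module load

    share_cols = {c: f"conc_{c}" for c in PRIMARY_CLASSES}
    prop_rows = []

    def proportions(df: pd.DataFrame, factor: str, level: str) -> None:
        shares = {
            c: float((df[col] / df["total_concentration"]).mean())
            for c, col in share_cols.items()
        }
        prop_rows.append({"factor": factor, "level": level, "n": len(df), **shares})

    proportions(base, "all", "all")
    for factor in ("collection_time", "gender", "age_group"):
        for level, sub in base.groupby(factor, observed=True):
            proportions(sub, factor, str(level))
    pd.DataFrame(prop_rows).to_csv(out_dir / "proportions.csv", index=False)

    mean_total = float(base["total_concentration"].mean())
    crystal_cols = [c for c in base.columns if c.startswith("crystals_")]
    crystal_positive = int(
        (base["crystals_OnlyBirefringence"] >= 3).sum()
    ) if "crystals_OnlyBirefringence" in base.columns else 0
    headline = {
        "n_samples": int(len(base)),
        "mean_total_concentration_per_mL": mean_total,
        "mean_identified_fraction": float(base["identified_fraction"].mean()),
        "mean_overall_area_um2": float(base["overall_mean_area"].mean()),
        "daily_particle_load": daily_load(mean_total, daily_volume_mL),
        "daily_volume_mL": daily_volume_mL,
        "mean_replicate_variability": float(
            base["replicate_variability"].dropna().mean()
        )
        if base["replicate_variability"].notna().any()
        else None,
        "crystal_positive_samples": crystal_positive,
        "crystal_sample_abundance": crystal_positive / len(base),
    }
    (out_dir / "report.json").write_text(json.dumps(headline, indent=1))
    return out_dir


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage under ``config.out_dir``; returns the output dir.

    With no ``input_dir``, a synthetic cohort is simulated first.  The
    run is a pure function of (inputs, config, seed).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    if config.input_dir is None:
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        in_dir = simulate_stage(spec, out / "cohort")
        _write_run_log(out, chash, "simulate")
    else:
        in_dir = Path(config.input_dir)
        if not in_dir.is_dir():
            raise FormatError(f"input directory {in_dir} does not exist")
    gate_stage(in_dir, out / "gated", config.gates)
    _write_run_log(out, chash, "gate")
    summarize_stage(in_dir, out / "gated", out / "summaries")
    _write_run_log(out, chash, "summarize")
    stats_stage(in_dir, out / "summaries", out / "stats",
                include_outliers=config.include_outliers)
    _write_run_log(out, chash, "stats")
    report_stage(in_dir, out / "summaries", out / "stats", out / "report",
                 config.daily_volume_mL)
    _write_run_log(out, chash, "report")
    return out
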