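"""Per-sample quantities derived from labeled events.

Concentrations are reported per millilitre of *original urine*: an event
count divides by the acquired volume of the concentrated suspension and by
the fold-concentration of the preparation (default 100×, i.e. a pellet
resuspended in 1/100 of the starting volume).

The equivalent diameter of a particle treats its imaged areal projection
as a circle: ``d = 2·sqrt(A/π)``.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import EmptySampleError, ValidationError
from .gating import CRYSTAL_METHODS, GatingResult, PRIMARY_CLASSES
from .io import EventTable, SampleRecord


def concentration(
    count: float, acquisition_volume_mL: float, concentration_factor: float
) -> float:
    """Particles per mL of original urine from an event count.

    ``count / (acquisition_volume_mL * concentration_factor)``.
    """
    if acquisition_volume_mL <= 0:
        raise ValidationError("acquisition_volume_mL must be > 0")
    if concentration_factor <= 0:
        raise ValidationError("concentration_factor must be > 0")
    if count < 0:
        raise ValidationError("count must be >= 0")
    return count / (acquisition_volume_mL * concentration_factor)


def equivalent_diameter(area_um2: float, ndigits: int | None = None) -> float:
    """Diameter (µm) of a circle with the given projected area (µm²).

    ``ndigits`` optionally rounds to the reporting precision (1 decimal
    place in the standard tables).
    """
    if area_um2 < 0:
        raise ValidationError("area must be >= 0")
    d = 2.0 * math.sqrt(area_um2 / math.pi)
    return round(d, ndigits) if ndigits is not None else d


def daily_load(total_concentration_per_mL: float, daily_volume_mL: float = 1400.0) -> float:
    """Particles excreted per day: concentration × daily urine volume.

    The normal 24-hour urine volume is 800–2,000 mL; 1,400 mL is the
    customary midpoint.
    """
    if total_concentration_per_mL < 0 or daily_volume_mL < 0:
        raise ValidationError("inputs must be >= 0")
    return total_concentration_per_mL * daily_volume_mL


@dataclasses.dataclass
class SampleSummary:
    """Per-sample, per-class quantification.

    ``concentrations`` and ``mean_areas`` are keyed by primary class;
    ``total_concentration`` is their sum.  A class with no events has
    concentration 0 and mean area NaN.
    """

    sample_id: str
    concentrations: dict[str, float]
    total_concentration: float
    mean_areas: dict[str, float]
    overall_mean_area: float
    identified_fraction: float
    event_count: int
    crystal_counts: dict[str, int]
    replicate_variability: float = float("nan")
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.concentrations.values()):
            raise ValidationError("concentrations must be >= 0")
        if not math.isclose(
            self.total_concentration,
            sum(self.concentrations.values()),
            rel_tol=1e-9,
            abs_tol=1e-9,
        ):
            raise ValidationError("total concentration must equal the class sum")
        if not 0.0 <= self.identified_fraction <= 1.0:
            raise ValidationError("identified_fraction must lie in [0, 1]")


def summarize_sample(
    result: GatingResult,
    table: EventTable,
    record: SampleRecord,
) -> SampleSummary:
    """Fill a :class:`SampleSummary` from one classified sample.

    The identified fraction is the share of non-bead events carrying any
    class other than Unidentified.  Crystal flags do not alter class
    membership; their event counts are reported alongside.
    """
    counts = result.counts
    total_events = sum(counts.values())
    if total_events == 0:
        raise EmptySampleError(f"sample {record.sample_id} has no non-bead events")
    vol = table.acquisition_volume_mL
    factor = record.concentration_factor
    concentrations = {
        cls: concentration(n, vol, factor) for cls, n in counts.items()
    }
    non_bead = result.labels.loc[~result.labels["is_bead"].astype(bool)]
    mean_areas: dict[str, float] = {}
    # areas joined on event_id so labels reloaded from disk still align
    areas = table.data.set_index("event_id")["bf_area"]
    for cls in PRIMARY_CLASSES:
        ids = non_bead.loc[non_bead["primary_class"] == cls, "event_id"]
        mean_areas[cls] = float(areas.loc[ids].mean()) if len(ids) else float("nan")
    overall_mean_area = float(areas.loc[non_bead["event_id"]].mean())
    identified = total_events - counts["Unidentified"]
    return SampleSummary(
        sample_id=record.sample_id,
        concentrations=concentrations,
        total_concentration=sum(concentrations.values()),
        mean_areas=mean_areas,
        overall_mean_area=overall_mean_area,
        identified_fraction=identified / total_events,
        event_count=total_events,
        crystal_counts=dict(result.crystal_counts),
    )


def merge_replicates(s1: SampleSummary, s2: SampleSummary | None = None) -> SampleSummary:
    """Average two replicate measurements of the same sample.

    Concentrations and mean areas become arithmetic means; the replicate
    variability is the absolute relative difference of the two total
    concentrations, ``|c1 − c2| / mean(c1, c2)``.  A single replicate
    passes through unchanged with variability NaN.
    """
    if s2 is None:
        return s1
    if s1.sample_id != s2.sample_id:
        raise ValidationError(
            f"replicates of different samples: {s1.sample_id} vs {s2.sample_id}"
        )
    conc = {
        c: (s1.concentrations[c] + s2.concentrations[c]) / 2.0
        for c in s1.concentrations
    }
    def _mean_area(c: str) -> float:
        vals = [v for v in (s1.mean_areas[c], s2.mean_areas[c]) if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    areas = {c: _mean_area(c) for c in s1.mean_areas}
    mean_total = (s1.total_concentration + s2.total_concentration) / 2.0
    variability = (
        abs(s1.total_concentration - s2.total_concentration) / mean_total
        if mean_total > 0
        else float("nan")
    )
    return SampleSummary(
        sample_id=s1.sample_id,
        concentrations=conc,
        total_concentration=sum(conc.values()),
        mean_areas=areas,
        overall_mean_area=(s1.overall_mean_area + s2.overall_mean_area) / 2.0,
        identified_fraction=(s1.identified_fraction + s2.identified_fraction) / 2.0,
        event_count=s1.event_count + s2.event_count,
        crystal_counts={
            m: s1.crystal_counts.get(m, 0) + s2.crystal_counts.get(m, 0)
            for m in CRYSTAL_METHODS
        },
        replicate_variability=variability,
        n_replicates=2,
    )


# ---------------------------------------------------------------------------
# CSV interchange with the stats module
# ---------------------------------------------------------------------------


def summaries_to_frame(summaries: Iterable[SampleSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "sample_id": s.sample_id,
            "total_concentration": s.total_concentration,
            "identified_fraction": s.identified_fraction,
            "overall_mean_area": s.overall_mean_area,
            "event_count": s.event_count,
            "replicate_variability": s.replicate_variability,
            "n_replicates": s.n_replicates,
        }
        for cls in PRIMARY_CLASSES:
            row[f"conc_{cls}"] = s.concentrations.get(cls, 0.0)
            row[f"area_{cls}"] = s.mean_areas.get(cls, float("nan"))
        for m, n in s.crystal_counts.items():
            row[f"crystals_{m}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def write_summaries(summaries: Iterable[SampleSummary], path: str | Path) -> Path:
    path = Path(path)
    summaries_to_frame(summaries).to_csv(path, index=False)
    return path


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
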