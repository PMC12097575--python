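"""Hierarchical gating of compensated event features into particle classes.

The hierarchy, applied to every compensated event table:

1. *Size window* — events with bright-field area outside
   ``[area_min, area_max]`` (instrument detection limits: 0.33 µm pixel
   resolution up to the 70 µm pre-filter mesh, i.e. 0.1–4900 µm²) are
   dropped with a logged count.
2. *Bead exclusion* — calibration beads run alongside every sample and are
   removed by their signature: small bright-field area with high side
   scatter.
3. *DNA gate* — events high in both Hoechst intensity and Hoechst max
   pixel are DNA-containing particles (cells, cell fragments, bacteria);
   within DNA, small objects are called bacteria.
4. *Tag dominance* — the remaining "non-cell" events are classified from
   their tag max pixels: Calcein-positive → Calcium; else both LipidTox-
   and Proteostat-positive → LipidProtein; else exactly one of the two →
   Lipid / Protein; else Unidentified.
5. *Crystal flags* — three complementary birefringence-based detectors are
   evaluated on the non-cell events.  Crystal flags are annotations kept
   separately from the primary classes: a flagged event still counts in
   its primary class.

All gates are axis-aligned thresholds collected in :class:`GateConfig`.
The published numeric anchors are the defaults (100 a.u. tag max pixel,
10⁵ a.u. Hoechst intensity, 0.1–4900 µm² size window); everything else is
instrument-dependent and configurable.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import EventTable, intensity_column, max_pixel_column

logger = logging.getLogger(__name__)

PRIMARY_CLASSES = ("DNA", "Lipid", "Protein", "LipidProtein", "Calcium", "Unidentified")
IDENTIFIED_CLASSES = ("DNA", "Lipid", "Protein", "LipidProtein", "Calcium")
CRYSTAL_METHODS = ("ByArea", "ByCalcein", "OnlyBirefringence")


@dataclasses.dataclass
class GateConfig:
    """Every numeric threshold of the gating hierarchy.

    Units: areas in µm², intensities and max pixels in arbitrary units.
    """

    bead_area_max: float = 15.0
    bead_ssc_min: float = 5000.0
    hoechst_intensity_min: float = 1e5
    tag_maxpixel_min: float = 100.0
    biref_high_min: float = 300.0
    biref_area_min: float = 15.0
    biref_calcein_min: float = 100.0
    crystal_other_tag_max: float = 100.0
    bacteria_area_max: float = 20.0
    area_min: float = 0.1
    area_max: float = 4900.0

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if getattr(self, field.name) < 0:
                raise ValidationError(f"{field.name} must be >= 0")
        if not self.area_min < self.area_max:
            raise ValidationError("area_min must be < area_max")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GateConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown gate thresholds in config: {sorted(unknown)}")
        return cls(**payload)


def calibrate_birefringence_threshold(
    blank: EventTable, quantile: float = 0.999
) -> float:
    """Birefringence "high" cut-off from a blank (PBS-only) acquisition.

    Returns the given quantile (default 99.9th percentile) of the blank's
    birefringence max-pixel distribution — everything a crystal-free run
    produces is below "high" by construction.
    """
    if len(blank) == 0:
        raise ValidationError("blank table is empty; cannot calibrate")
    mp = blank.data[max_pixel_column("Birefringence")].to_numpy(dtype=float)
    return float(np.quantile(mp, quantile))


@dataclasses.dataclass
class GatingResult:
    """Per-event labels plus bookkeeping counts for one sample."""

    labels: pd.DataFrame  # aligned with the (size-filtered) event rows
    counts: dict[str, int]  # per primary class, over non-bead events
    crystal_counts: dict[str, int]  # per detection method
    n_beads: int
    n_size_dropped: int

    @property
    def n_particles(self) -> int:
        return int(sum(self.counts.values()))


# ---------------------------------------------------------------------------
# Stage masks (vectorized; operate on the underlying frame)
# ---------------------------------------------------------------------------


def _size_mask(df: pd.DataFrame, cfg: GateConfig) -> np.ndarray:
    area = df["bf_area"].to_numpy(dtype=float)
    return (area >= cfg.area_min) & (area <= cfg.area_max)


def _bead_mask(df: pd.DataFrame, cfg: GateConfig) -> np.ndarray:
    area = df["bf_area"].to_numpy(dtype=float)
    ssc = df["ssc_intensity"].to_numpy(dtype=float)
    return (area <= cfg.bead_area_max) & (ssc >= cfg.bead_ssc_min)


def _dna_mask(df: pd.DataFrame, cfg: GateConfig) -> np.ndarray:
    inten = df[intensity_column("Hoechst")].to_numpy(dtype=float)
    mp = df[max_pixel_column("Hoechst")].to_numpy(dtype=float)
    return (inten > cfg.hoechst_intensity_min) & (mp > cfg.tag_maxpixel_min)


def _subset(table: EventTable, mask: np.ndarray) -> EventTable:
    return EventTable(
        table.data.loc[mask].reset_index(drop=True),
        table.channel_names,
        table.acquisition_volume_mL,
    )


# ---------------------------------------------------------------------------
# Public stage operations
# ---------------------------------------------------------------------------


def exclude_beads(
    table: EventTable, cfg: GateConfig
) -> tuple[EventTable, EventTable]:
    """Split a compensated table into (particles, beads).

    Beads are events with ``bf_area <= bead_area_max`` **and**
    ``ssc_intensity >= bead_ssc_min``; the partition is exhaustive and
    disjoint.
    """
    mask = _bead_mask(table.data, cfg)
    if len(table) and mask.all():
        logger.warning("all %d events match the bead signature", len(table))
    return _subset(table, ~mask), _subset(table, mask)


def gate_dna(table: EventTable, cfg: GateConfig) -> tuple[EventTable, EventTable]:
    """Split bead-excluded events into (dna, non_cells).

    DNA events exceed both the Hoechst intensity threshold (default 10⁵
    a.u.) and the Hoechst max-pixel threshold (default 100 a.u.).
    """
    mask = _dna_mask(table.data, cfg)
    return _subset(table, mask), _subset(table, ~mask)


def dna_subclass(dna: EventTable, cfg: GateConfig) -> pd.Series:
    """Within the DNA population, split bacteria from cells by area."""
    area = dna.data["bf_area"].to_numpy(dtype=float)
    return pd.Series(
        np.where(area <= cfg.bacteria_area_max, "bacteria", "cell"),
        index=dna.data.index,
        name="dna_subclass",
    )


def classify_tags(non_cells: EventTable, cfg: GateConfig) -> pd.Series:
    """Assign each non-cell event exactly one primary class.

    Positivity is ``max_pixel[tag] > tag_maxpixel_min`` per tag.  The
    precedence resolving multi-positive events is Calcein first (calcium
    particles are reported independently of their lipid/protein content),
    then the LipidTox+Proteostat mixture, then the single tags.
    """
    df = non_cells.data
    cal = df[max_pixel_column("Calcein")].to_numpy(dtype=float) > cfg.tag_maxpixel_min
    lip = df[max_pixel_column("LipidTox")].to_numpy(dtype=float) > cfg.tag_maxpixel_min
    pro = df[max_pixel_column("Proteostat")].to_numpy(dtype=float) > cfg.tag_maxpixel_min
    labels = np.full(len(df), "Unidentified", dtype=object)
    labels[pro] = "Protein"
    labels[lip] = "Lipid"
    labels[lip & pro] = "LipidProtein"
    labels[cal] = "Calcium"
    return pd.Series(labels, index=df.index, name="primary_class")


def detect_crystals(
    non_cells: EventTable, method: str, cfg: GateConfig
) -> pd.Series:
    """Flag candidate crystals among non-cell events.

    Three complementary detectors:

    ``ByArea``
        high birefringence max pixel on a large object;
    ``ByCalcein``
        high birefringence max pixel together with Calcein positivity
        (calcium-bearing crystals such as calcium oxalate);
    ``OnlyBirefringence``
        high birefringence *intensity* with minimal signal in every other
        tag (LipidTox, Proteostat, Hoechst) — true crystals carry no
        biological stain.
    """
    if method not in CRYSTAL_METHODS:
        raise ValidationError(
            f"unknown crystal method {method!r}; expected one of {CRYSTAL_METHODS}"
        )
    df = non_cells.data
    biref_mp = df[max_pixel_column("Birefringence")].to_numpy(dtype=float)
    if method == "ByArea":
        flag = (biref_mp >= cfg.biref_high_min) & (
            df["bf_area"].to_numpy(dtype=float) >= cfg.biref_area_min
        )
    elif method == "ByCalcein":
        cal_mp = df[max_pixel_column("Calcein")].to_numpy(dtype=float)
        flag = (biref_mp >= cfg.biref_high_min) & (cal_mp >= cfg.biref_calcein_min)
    else:  # OnlyBirefringence
        biref_int = df[intensity_column("Birefringence")].to_numpy(dtype=float)
        others = np.column_stack(
            [
                df[max_pixel_column(ch)].to_numpy(dtype=float)
                for ch in ("LipidTox", "Proteostat", "Hoechst")
            ]
        )
        flag = (biref_int >= cfg.biref_high_min) & (
            others <= cfg.crystal_other_tag_max
        ).all(axis=1)
    return pd.Series(flag, index=df.index, name=f"crystal_{method}")


def classify_sample(table: EventTable, cfg: GateConfig | None = None) -> GatingResult:
    """Run the full hierarchy on one compensated sample.

    Returns per-event labels (primary class, bead flag, DNA subclass and
    the three crystal flags) plus per-class counts.  Counts over the six
    primary classes sum to the non-bead event count inside the size
    window.
    """
    cfg = cfg or GateConfig()
    size_ok = _size_mask(table.data, cfg)
    n_dropped = int((~size_ok).sum())
    if n_dropped:
        logger.info("dropped %d events outside the %g-%g um^2 size window",
                    n_dropped, cfg.area_min, cfg.area_max)
    sized = _subset(table, size_ok)

    particles, beads = exclude_beads(sized, cfg)
    dna, non_cells = gate_dna(particles, cfg)

    labels = pd.DataFrame(index=sized.data.index)
    bead_mask = _bead_mask(sized.data, cfg)
    labels["is_bead"] = bead_mask
    labels["primary_class"] = pd.NA
    labels["dna_subclass"] = "none"
    for m in CRYSTAL_METHODS:
        labels[f"crystal_{m}"] = False

    particle_idx = sized.data.index[~bead_mask]
    dna_mask = _dna_mask(sized.data, cfg) & ~bead_mask
    labels.loc[dna_mask, "primary_class"] = "DNA"
    labels.loc[dna_mask, "dna_subclass"] = np.where(
        sized.data.loc[dna_mask, "bf_area"].to_numpy(dtype=float)
        <= cfg.bacteria_area_max,
        "bacteria",
        "cell",
    )
    non_cell_idx = particle_idx[~dna_mask[~bead_mask]] if len(particle_idx) else particle_idx

    tag_labels = classify_tags(non_cells, cfg)
    labels.loc[non_cell_idx, "primary_class"] = tag_labels.to_numpy()
    crystal_counts = {}
    for m in CRYSTAL_METHODS:
        flags = detect_crystals(non_cells, m, cfg)
        labels.loc[non_cell_idx, f"crystal_{m}"] = flags.to_numpy()
        crystal_counts[m] = int(flags.sum())

    class_col = labels.loc[~bead_mask, "primary_class"]
    counts = {c: int((class_col == c).sum()) for c in PRIMARY_CLASSES}
    if "event_id" in sized.data.columns:
        labels.insert(0, "event_id", sized.data["event_id"].to_numpy())
    return GatingResult(
        labels=labels,
        counts=counts,
        crystal_counts=crystal_counts,
        n_beads=int(bead_mask.sum()),
        n_size_dropped=n_dropped,
    )
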