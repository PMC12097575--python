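"""Event-table and manifest I/O.

An *event table* holds one row per imaged particle with the features used
throughout the pipeline: bright-field area (µm²), side-scatter intensity
(a.u.), and, for each fluorescence channel, the total intensity and the
max-pixel (brightest single pixel) value, both in arbitrary units.

Two on-disk formats are supported:

* CSV — comma separated, header row, UTF-8, "." decimal; the interchange
  format for every intermediate product of the pipeline.
* FCS 3.0/3.1 — list-mode, single dataset, ``$DATATYPE F`` (32-bit float).
  The reader/writer here covers exactly that profile, which is what the
  synthetic generator emits and what most cytometry exports provide.

Instrument files rarely label parameters with semantic names ("Ch07" rather
than "intensity_Hoechst"), so every reader accepts a *channel map* from the
labels found in the file to the semantic feature names listed in
:data:`FEATURE_COLUMNS`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ChannelMappingError, FormatError, ValidationError

#: Fluorescence channels, in canonical order.
CHANNELS: tuple[str, ...] = (
    "Hoechst",
    "Calcein",
    "LipidTox",
    "Proteostat",
    "Birefringence",
)

#: Morphology/scatter features every event carries.
MORPHOLOGY_COLUMNS: tuple[str, ...] = ("bf_area", "ssc_intensity")

#: All numeric feature columns of an event table, in canonical order.
FEATURE_COLUMNS: tuple[str, ...] = MORPHOLOGY_COLUMNS + tuple(
    f"{kind}_{ch}" for ch in CHANNELS for kind in ("intensity", "max_pixel")
)

#: Stable integer codes used to carry ground-truth labels through FCS files.
TRUTH_CODES: dict[str, int] = {
    "Unidentified": 0,
    "Lipid": 1,
    "Protein": 2,
    "LipidProtein": 3,
    "Calcium": 4,
    "DNA_cell": 5,
    "DNA_bacteria": 6,
    "Bead": 7,
    "Crystal": 8,
}
_CODE_TO_TRUTH = {v: k for k, v in TRUTH_CODES.items()}

GENDERS = ("female", "male")
AGE_GROUPS = ("younger", "middle", "older")
COLLECTION_TIMES = ("FIM", "LM")
DAY_INDICES = (1, 2, 3)
REPLICATE_INDICES = (1, 2)

MANIFEST_COLUMNS = (
    "sample_id",
    "participant_id",
    "gender",
    "age_group",
    "collection_time",
    "day_index",
    "replicate_index",
    "concentration_factor",
    "outlier_flag",
)


def intensity_column(channel: str) -> str:
    return f"intensity_{channel}"


def max_pixel_column(channel: str) -> str:
    return f"max_pixel_{channel}"


@dataclasses.dataclass
class EventTable:
    """Per-event feature table for one sample measurement.

    Attributes
    ----------
    data
        One row per event. Must contain every column in
        :data:`FEATURE_COLUMNS`; an ``event_id`` column and a
        ``truth_label`` column (synthetic data only) are optional and
        preserved where the format allows.
    channel_names
        Ordered fluorescence channel list (defaults to :data:`CHANNELS`).
    acquisition_volume_mL
        Volume of the concentrated suspension acquired during the run, mL.
    """

    data: pd.DataFrame
    channel_names: tuple[str, ...] = CHANNELS
    acquisition_volume_mL: float = 1.0

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.validate()

    def validate(self) -> None:
        if self.acquisition_volume_mL <= 0:
            raise ValidationError("acquisition_volume_mL must be > 0")
        missing = [c for c in FEATURE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ChannelMappingError(f"event table missing feature columns: {missing}")
        if "event_id" not in self.data.columns:
            self.data = self.data.copy()
            self.data.insert(0, "event_id", np.arange(len(self.data)))
        if len(self.data) == 0:
            return
        feats = self.data[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        if not np.isfinite(feats).all():
            raise ValidationError("event features must be finite")
        if (feats < 0).any():
            raise ValidationError("areas, intensities and max pixels must be >= 0")
        for ch in self.channel_names:
            mp = self.data[max_pixel_column(ch)].to_numpy(dtype=float)
            it = self.data[intensity_column(ch)].to_numpy(dtype=float)
            # max pixel is one pixel of the summed signal; tolerate float32 rounding
            if (mp > it * (1 + 1e-5) + 1e-9).any():
                raise ValidationError(f"max_pixel exceeds intensity in channel {ch}")

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "EventTable":
        return EventTable(
            self.data.copy(), self.channel_names, self.acquisition_volume_mL
        )

    def intensities(self) -> np.ndarray:
        """(n_events, n_channels) float array of total intensities."""
        cols = [intensity_column(c) for c in self.channel_names]
        return self.data[cols].to_numpy(dtype=float)

    def max_pixels(self) -> np.ndarray:
        cols = [max_pixel_column(c) for c in self.channel_names]
        return self.data[cols].to_numpy(dtype=float)


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """One row of the cohort manifest."""

    sample_id: str
    participant_id: str
    gender: str
    age_group: str
    collection_time: str
    day_index: int
    replicate_index: int
    concentration_factor: float = 100.0
    outlier_flag: bool = False

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValidationError(f"unknown gender {self.gender!r}; expected {GENDERS}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"unknown age_group {self.age_group!r}; expected {AGE_GROUPS}"
            )
        if self.collection_time not in COLLECTION_TIMES:
            raise ValidationError(
                f"unknown collection_time {self.collection_time!r}; "
                f"expected {COLLECTION_TIMES}"
            )
        if self.day_index not in DAY_INDICES:
            raise ValidationError(f"day_index must be one of {DAY_INDICES}")
        if self.replicate_index not in REPLICATE_INDICES:
            raise ValidationError(f"replicate_index must be one of {REPLICATE_INDICES}")
        if self.concentration_factor <= 0:
            raise ValidationError("concentration_factor must be > 0")


# ---------------------------------------------------------------------------
# CSV event tables
# ---------------------------------------------------------------------------


def _apply_channel_map(
    df: pd.DataFrame, channel_map: Mapping[str, str] | None
) -> pd.DataFrame:
    if channel_map:
        df = df.rename(columns=dict(channel_map))
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ChannelMappingError(
            f"input lacks required features {missing}; provide a channel map "
            f"from instrument labels to semantic names"
        )
    return df


def read_event_table(
    path: str | Path,
    format: str = "table",
    *,
    channel_map: Mapping[str, str] | None = None,
    acquisition_volume_mL: float | None = None,
) -> EventTable:
    """Read an event table from ``path``.

    Parameters
    ----------
    format
        ``"table"`` (CSV) or ``"fcs"``.
    channel_map
        Optional mapping from labels found in the file to semantic feature
        names (``bf_area``, ``intensity_Hoechst``, ...).
    acquisition_volume_mL
        Overrides the volume stored in (or absent from) the file.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "table":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error variety
            raise FormatError(f"cannot parse CSV event table {path}: {exc}") from exc
        volume = acquisition_volume_mL
        if volume is None:
            volume = _read_csv_volume_sidecar(path)
        df = _apply_channel_map(df, channel_map)
        return EventTable(df, CHANNELS, volume if volume is not None else 1.0)
    if format == "fcs":
        return read_fcs(
            path, channel_map=channel_map, acquisition_volume_mL=acquisition_volume_mL
        )
    raise ValidationError(f"unknown event-table format {format!r}")


def write_event_table(table: EventTable, path: str | Path, format: str = "table") -> Path:
    """Write ``table`` to ``path``; the result round-trips through
    :func:`read_event_table` losslessly at the format's declared precision
    (exact for CSV, float32 for FCS)."""
    path = Path(path)
    if format == "table":
        cols = ["event_id", *FEATURE_COLUMNS]
        if "truth_label" in table.data.columns:
            cols.append("truth_label")
        try:
            table.data[cols].to_csv(path, index=False)
        except OSError as exc:
            raise FormatError(f"cannot write {path}: {exc}") from exc
        _write_csv_volume_sidecar(path, table.acquisition_volume_mL)
        return path
    if format == "fcs":
        return write_fcs(table, path)
    raise ValidationError(f"unknown event-table format {format!r}")


def _volume_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".volume")


def _write_csv_volume_sidecar(path: Path, volume: float) -> None:
    _volume_sidecar(path).write_text(f"{volume!r}\n")


def _read_csv_volume_sidecar(path: Path) -> float | None:
    sidecar = _volume_sidecar(path)
    if sidecar.exists():
        return float(sidecar.read_text().strip())
    return None


# ---------------------------------------------------------------------------
# FCS 3.0 (list mode, $DATATYPE F)
# ---------------------------------------------------------------------------

_FCS_VOLUME_KEY = "UROFLOW_VOL_ML"


def write_fcs(table: EventTable, path: str | Path) -> Path:
    """Write a single-dataset FCS 3.0 file (float32 list mode).

    ``event_id`` is not stored (row order is the identity); a ``truth_label``
    column, when present, is stored as the numeric parameter ``truth_code``
    using :data:`TRUTH_CODES`.
    """
    path = Path(path)
    params = list(FEATURE_COLUMNS)
    mat = table.data[params].to_numpy(dtype="<f4")
    if "truth_label" in table.data.columns:
        codes = (
            table.data["truth_label"].map(TRUTH_CODES).fillna(-1).to_numpy(dtype="<f4")
        )
        mat = np.column_stack([mat, codes]).astype("<f4")
        params.append("truth_code")
    n_events, n_par = mat.shape
    data_bytes = mat.tobytes()

    delim = "/"
    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$TOT", str(n_events)),
        ("$PAR", str(n_par)),
        (_FCS_VOLUME_KEY, repr(table.acquisition_volume_mL)),
    ]
    for i, name in enumerate(params, start=1):
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(1.0, float(mat[:, i - 1].max(initial=0.0)) + 1)))),
        ]

    def render(begin_data: int, end_data: int) -> bytes:
        # zero-padded offsets keep the TEXT length independent of their values
        kws = [
            ("$BEGINDATA", str(begin_data).zfill(10)),
            ("$ENDDATA", str(end_data).zfill(10)),
        ] + keywords
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in kws) + delim
        return text.encode("ascii")

    header_len = 58
    text = render(0, 0)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(data_bytes) - 1 if data_bytes else 0
    text = render(data_start, data_end)
    assert text_end == text_start + len(text) - 1

    def off(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:  # offsets beyond the 8-char header field live in TEXT only
            s = "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.0    " + off(text_start) + off(text_end)
    header += off(data_start if data_end else 0) + off(data_end)
    header += off(0) + off(0)
    assert len(header) == header_len
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(text)
            fh.write(data_bytes)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc
    return path


def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty FCS TEXT segment")
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)[1:]
    if parts and parts[-1] == "":
        parts = parts[:-1]
    if len(parts) % 2:
        raise FormatError("malformed FCS TEXT segment (odd token count)")
    return {parts[i].strip().upper() if parts[i].startswith("$") else parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(
    path: str | Path,
    *,
    channel_map: Mapping[str, str] | None = None,
    acquisition_volume_mL: float | None = None,
) -> EventTable:
    """Read a list-mode FCS 3.0/3.1 file with ``$DATATYPE F`` data."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58 or not blob[:6] in (b"FCS3.0", b"FCS3.1"):
        raise FormatError(f"{path} is not an FCS 3.0/3.1 file")

    def header_off(field: int) -> int:
        seg = blob[10 + 8 * field : 18 + 8 * field].strip()
        return int(seg) if seg else 0

    text_start, text_end = header_off(0), header_off(1)
    kw = _parse_fcs_text(blob[text_start : text_end + 1])
    data_start = int(kw.get("$BEGINDATA", header_off(2)) or header_off(2))
    data_end = int(kw.get("$ENDDATA", header_off(3)) or header_off(3))
    if kw.get("$DATATYPE", "F").upper() != "F":
        raise FormatError("only $DATATYPE F (float) FCS data is supported")
    if kw.get("$MODE", "L").upper() != "L":
        raise FormatError("only list-mode ($MODE L) FCS data is supported")
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    dtype = "<f4" if byteord.startswith("1") else ">f4"
    raw = blob[data_start : data_end + 1]
    expected = 4 * n_par * n_tot
    if len(raw) < expected:
        raise FormatError(f"truncated FCS data segment in {path}")
    mat = np.frombuffer(raw[:expected], dtype=dtype).reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    df = pd.DataFrame(np.asarray(mat, dtype=float), columns=names)
    if "truth_code" in df.columns:
        df["truth_label"] = df.pop("truth_code").map(
            lambda c: _CODE_TO_TRUTH.get(int(c), "Unidentified")
        )
    df = _apply_channel_map(df, channel_map)
    volume = acquisition_volume_mL
    if volume is None and _FCS_VOLUME_KEY in kw:
        volume = float(kw[_FCS_VOLUME_KEY])
    return EventTable(df, CHANNELS, volume if volume is not None else 1.0)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read and validate the cohort sample manifest (CSV)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                participant_id=str(row.participant_id),
                gender=str(row.gender),
                age_group=str(row.age_group),
                collection_time=str(row.collection_time),
                day_index=int(row.day_index),
                replicate_index=int(row.replicate_index),
                concentration_factor=float(row.concentration_factor),
                outlier_flag=_as_bool(row.outlier_flag),
            )
        )
    return records


def write_manifest(records: Iterable[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return path


def manifest_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=MANIFEST_COLUMNS)


def _as_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", ""):
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean outlier_flag")
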