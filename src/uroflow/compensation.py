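"""Fluorescence spillover estimation and compensation.

A dye excited for one detector leaks a fixed fraction of its signal into
the others.  With spillover matrix ``S`` (rows: source channel, columns:
detected channel, diagonal 1), the detected intensity vector ``x`` of an
event relates to the true per-dye signal ``y`` by ``x = Sᵀ·y``.
Compensation solves that linear system per event.

The spillover coefficients are estimated from single-stain controls: among
events positive for the stained channel, entry ``(i, j)`` is the median of
the per-event ratio ``x_j / x_i`` — a robust, parameter-free slope through
the origin that resists the heavy tails typical of cytometry intensities.

Max-pixel features are nonlinear in the pixel image, so they are not
unmixed independently; each event's max pixel is scaled per channel by the
same correction ratio the unmixing applied to that channel's intensity,
which preserves its ordering relative to intensity.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    InsufficientControlError,
    NonPhysicalSpilloverError,
    NumericError,
    ValidationError,
)
from .io import CHANNELS, EventTable, intensity_column, max_pixel_column


@dataclasses.dataclass
class SpilloverMatrix:
    """Square channel-crosstalk matrix, indexed (source, detected)."""

    matrix: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.channels = tuple(self.channels)
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise ValidationError(
                f"spillover matrix shape {self.matrix.shape} does not match "
                f"{n} channels"
            )
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValidationError("spillover diagonal entries must equal 1")
        off = self.matrix[~np.eye(n, dtype=bool)]
        if (off < 0).any() or (off >= 1).any():
            raise NonPhysicalSpilloverError(
                "off-diagonal spillover must lie in [0, 1)"
            )
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise NumericError("spillover matrix is singular")

    @classmethod
    def identity(cls, channels: tuple[str, ...] = CHANNELS) -> "SpilloverMatrix":
        return cls(np.eye(len(channels)), channels)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.matrix, index=self.channels, columns=self.channels).to_csv(
            path
        )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), tuple(df.columns))


def estimate_spillover(
    controls: Mapping[str, EventTable],
    *,
    positive_threshold: float | Mapping[str, float] = 100.0,
    min_positive_events: int = 10,
    channels: tuple[str, ...] = CHANNELS,
) -> SpilloverMatrix:
    """Estimate a spillover matrix from single-stain control tables.

    Parameters
    ----------
    controls
        One :class:`EventTable` per fluorescent channel; the key names the
        stained channel.
    positive_threshold
        Intensity above which a control event counts as positive for its
        stained channel, either one value or per channel.  The default of
        100 a.u. matches the identification cut-off used downstream; in
        practice it should be set from an unstained region (e.g. its 95th
        percentile).
    min_positive_events
        Minimum positive events a control must supply.
    """
    n = len(channels)
    S = np.eye(n)
    for i, ch in enumerate(channels):
        if ch not in controls:
            raise ValidationError(f"missing single-stain control for channel {ch}")
        table = controls[ch]
        thr = (
            positive_threshold[ch]
            if isinstance(positive_threshold, Mapping)
            else positive_threshold
        )
        x = table.intensities()
        pos = x[:, i] > thr if len(x) else np.zeros(0, dtype=bool)
        n_pos = int(pos.sum())
        if n_pos < min_positive_events:
            raise InsufficientControlError(
                f"control for {ch} has {n_pos} positive events "
                f"(minimum {min_positive_events})"
            )
        src = x[pos, i]
        for j in range(n):
            if j == i:
                continue
            slope = float(np.median(x[pos, j] / src))
            if slope >= 1:
                raise NonPhysicalSpilloverError(
                    f"estimated spillover {ch}->{channels[j]} = {slope:.3f} >= 1"
                )
            S[i, j] = max(slope, 0.0)
    return SpilloverMatrix(S, channels)


def apply_compensation(table: EventTable, spillover: SpilloverMatrix) -> EventTable:
    """Return a new table with unmixed fluorescence values.

    Solves ``Sᵀ·y = x`` for every event, scales max pixels by the per-event
    per-channel correction ratio ``y_c / x_c``, clamps negative results to
    zero, and leaves ``bf_area`` and ``ssc_intensity`` untouched.
    """
    if tuple(table.channel_names) != tuple(spillover.channels):
        raise ValidationError(
            "channel order of table and spillover matrix disagree: "
            f"{table.channel_names} vs {spillover.channels}"
        )
    out = table.copy()
    if len(table) == 0:
        return out
    x = table.intensities()
    try:
        y = np.linalg.solve(spillover.matrix.T, x.T).T
    except np.linalg.LinAlgError as exc:
        raise NumericError(f"spillover matrix not invertible: {exc}") from exc
    mp = table.max_pixels()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x > 0, y / np.where(x > 0, x, 1.0), 1.0)
    mp_comp = np.clip(mp * ratio, 0.0, None)
    y = np.clip(y, 0.0, None)
    mp_comp = np.minimum(mp_comp, y)  # preserve max_pixel <= intensity after clamping
    for k, ch in enumerate(table.channel_names):
        out.data[intensity_column(ch)] = y[:, k]
        out.data[max_pixel_column(ch)] = mp_comp[:, k]
    return out
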