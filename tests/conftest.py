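import numpy as np
import pandas as pd
import pytest

from uroflow.io import CHANNELS, EventTable, intensity_column, max_pixel_column
from uroflow.synthdata import (
    SyntheticCohortSpec,
    default_spillover,
    generate_controls,
    generate_event_table,
)


def make_table(rows: list[dict], volume: float = 1.0) -> EventTable:
    """Build an EventTable from sparse per-event dicts; unmentioned
    features default to 0 (intensities track max pixels at 10x)."""
    records = []
    for i, row in enumerate(rows):
        rec = {"event_id": i, "bf_area": row.get("bf_area", 1.0),
               "ssc_intensity": row.get("ssc_intensity", 100.0)}
        for ch in CHANNELS:
            mp = row.get(ch, 0.0)
            rec[max_pixel_column(ch)] = mp
            rec[intensity_column(ch)] = row.get(f"{ch}_intensity", mp * 10.0)
        records.append(rec)
    columns = ["event_id", "bf_area", "ssc_intensity"] + [
        col(ch) for ch in CHANNELS for col in (max_pixel_column, intensity_column)
    ]
    df = pd.DataFrame(records, columns=columns).astype(
        {c: float for c in columns if c != "event_id"}
    )
    return EventTable(df, CHANNELS, volume)


@pytest.fixture
def sparse_table_factory():
    return make_table


@pytest.fixture(scope="session")
def spillover():
    return default_spillover()


@pytest.fixture(scope="session")
def controls(spillover):
    return generate_controls(11, spillover, n_events=500)


@pytest.fixture(scope="session")
def sample_table(spillover):
    """Mid-sized synthetic sample with truth labels (unmixed signals)."""
    return generate_event_table(n_events=50_000, seed=11, spillover=spillover)


@pytest.fixture(scope="session")
def tiny_cohort_spec():
    """One participant per gender x age cell, small tables: fast cohort."""
    return SyntheticCohortSpec(
        participants_per_group=1,
        events_per_sample=2_000,
        n_replicated_samples=12,
        seed=5,
    )
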