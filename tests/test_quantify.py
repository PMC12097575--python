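import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uroflow.compensation import apply_compensation
from uroflow.errors import EmptySampleError, ValidationError
from uroflow.gating import GateConfig, classify_sample
from uroflow.io import SampleRecord
from uroflow.quantify import (
    concentration,
    daily_load,
    equivalent_diameter,
    merge_replicates,
    summaries_to_frame,
    summarize_sample,
)
from uroflow.synthdata import generate_event_table


def _record(sample_id="s1", replicate=1, factor=100.0):
    return SampleRecord(sample_id, "P01", "female", "younger", "FIM", 1,
                        replicate, concentration_factor=factor)


class TestConcentration:
    @pytest.mark.parametrize(
        "count,volume,factor,expected",
        [
            (22_600, 0.001, 100.0, 226e3),  # headline total, illustrative volume
            (0, 0.001, 100.0, 0.0),
            (1_000, 0.01, 100.0, 1_000.0),
        ],
    )
    def test_arithmetic(self, count, volume, factor, expected):
        assert concentration(count, volume, factor) == pytest.approx(expected)

    @pytest.mark.parametrize("volume,factor", [(0.0, 100.0), (0.001, 0.0), (-1.0, 100.0)])
    def test_nonpositive_inputs_rejected(self, volume, factor):
        with pytest.raises(ValidationError):
            concentration(100, volume, factor)

    @given(st.integers(0, 10**6), st.floats(1e-6, 1.0), st.floats(1.0, 1000.0))
    @settings(max_examples=50, deadline=None)
    def test_doubling_factor_halves_concentration(self, count, volume, factor):
        c1 = concentration(count, volume, factor)
        c2 = concentration(count, volume, 2 * factor)
        assert c2 == pytest.approx(c1 / 2)


class TestEquivalentDiameter:
    @pytest.mark.parametrize(
        "area,expected",
        [(4.3, 2.3), (7.0, 3.0), (9.3, 3.4), (207.0, 16.2), (math.pi, 2.0)],
    )
    def test_published_mean_areas(self, area, expected):
        assert equivalent_diameter(area, ndigits=1) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValidationError):
            equivalent_diameter(-1.0)

    @given(st.floats(1e-6, 4900.0))
    @settings(max_examples=100, deadline=None)
    def test_inverts_circle_area(self, area):
        d = equivalent_diameter(area)
        assert math.pi * (d / 2) ** 2 == pytest.approx(area, rel=1e-9)

    def test_strictly_increasing(self):
        areas = np.linspace(0.1, 4900, 200)
        diams = [equivalent_diameter(a) for a in areas]
        assert all(d2 > d1 for d1, d2 in zip(diams, diams[1:]))


class TestDailyLoad:
    def test_headline_daily_load(self):
        # 226e3 particles/mL x 1400 mL/day
        assert daily_load(226e3, 1400.0) == pytest.approx(316.4e6)

    @pytest.mark.parametrize("conc,vol,expected", [(0.0, 1400.0, 0.0), (100.0, 1000.0, 1e5)])
    def test_arithmetic(self, conc, vol, expected):
        assert daily_load(conc, vol) == expected


@pytest.fixture(scope="module")
def classified(spillover):
    table = generate_event_table(n_events=30_000, seed=17, spillover=spillover,
                                 acquisition_volume_mL=0.003)
    result = classify_sample(apply_compensation(table, spillover), GateConfig())
    return table, result


class TestSummarizeSample:
    def test_identified_fraction_matches_generated_mix(self, classified):
        """Default mix (Lipid .06, Protein .13, LipidProtein .23,
        Calcium .02, DNA .01) gives identified fraction ~0.45."""
        table, result = classified
        summary = summarize_sample(result, table, _record())
        n = summary.event_count
        tol = 3 * math.sqrt(0.45 * 0.55 / n)
        assert summary.identified_fraction == pytest.approx(0.45, abs=tol + 0.01)

    def test_total_is_sum_of_class_concentrations(self, classified):
        table, result = classified
        summary = summarize_sample(result, table, _record())
        assert summary.total_concentration == pytest.approx(
            sum(summary.concentrations.values())
        )
        assert summary.total_concentration == pytest.approx(
            summary.event_count / (0.003 * 100.0)
        )

    def test_all_unidentified_gives_zero_identified_fraction(self, sparse_table_factory):
        table = sparse_table_factory([{} for _ in range(20)])
        result = classify_sample(table, GateConfig())
        summary = summarize_sample(result, table, _record())
        assert summary.identified_fraction == 0.0

    def test_empty_class_zero_concentration_nan_area(self, sparse_table_factory):
        table = sparse_table_factory([{"LipidTox": 500.0}])
        result = classify_sample(table, GateConfig())
        summary = summarize_sample(result, table, _record())
        assert summary.concentrations["Calcium"] == 0.0
        assert math.isnan(summary.mean_areas["Calcium"])
        assert summary.concentrations["Lipid"] > 0

    def test_empty_sample_rejected(self, sparse_table_factory):
        table = sparse_table_factory([])
        result = classify_sample(table, GateConfig())
        with pytest.raises(EmptySampleError):
            summarize_sample(result, table, _record())


class TestMergeReplicates:
    def _summary(self, total, sample_id="s1"):
        table = generate_event_table(n_events=1000, seed=int(total) % 997,
                                     acquisition_volume_mL=1000.0 / (total * 100.0))
        result = classify_sample(table, GateConfig())
        return summarize_sample(result, table, _record(sample_id))

    def test_identical_replicates_zero_variability(self, classified):
        table, result = classified
        s = summarize_sample(result, table, _record())
        merged = merge_replicates(s, s)
        assert merged.replicate_variability == 0.0
        assert merged.total_concentration == pytest.approx(s.total_concentration)

    def test_forty_percent_variability_example(self, classified):
        """Totals 200e3 and 300e3 merge to 250e3 with variability 0.40."""
        table, result = classified
        s1 = summarize_sample(result, table, _record())
        scale1 = 200e3 / s1.total_concentration
        scale2 = 300e3 / s1.total_concentration
        import dataclasses as dc
        a = dc.replace(
            s1,
            concentrations={k: v * scale1 for k, v in s1.concentrations.items()},
            total_concentration=s1.total_concentration * scale1,
        )
        b = dc.replace(
            s1,
            concentrations={k: v * scale2 for k, v in s1.concentrations.items()},
            total_concentration=s1.total_concentration * scale2,
        )
        merged = merge_replicates(a, b)
        assert merged.total_concentration == pytest.approx(250e3)
        assert merged.replicate_variability == pytest.approx(0.40)

    def test_merge_symmetric(self, classified):
        table, result = classified
        s1 = summarize_sample(result, table, _record())
        import dataclasses as dc
        s2 = dc.replace(
            s1,
            concentrations={k: v * 1.5 for k, v in s1.concentrations.items()},
            total_concentration=s1.total_concentration * 1.5,
        )
        m12, m21 = merge_replicates(s1, s2), merge_replicates(s2, s1)
        assert m12.total_concentration == pytest.approx(m21.total_concentration)
        assert m12.replicate_variability == pytest.approx(m21.replicate_variability)

    def test_single_replicate_passes_through(self, classified):
        table, result = classified
        s = summarize_sample(result, table, _record())
        merged = merge_replicates(s, None)
        assert merged is s
        assert math.isnan(merged.replicate_variability)

    def test_mismatched_sample_ids_rejected(self, classified):
        table, result = classified
        s1 = summarize_sample(result, table, _record("s1"))
        s2 = summarize_sample(result, table, _record("s2"))
        with pytest.raises(ValidationError):
            merge_replicates(s1, s2)


def test_summaries_frame_has_one_row_per_sample(classified):
    table, result = classified
    s = summarize_sample(result, table, _record())
    df = summaries_to_frame([s, s])
    assert len(df) == 2
    assert "conc_LipidProtein" in df.columns
    assert df["total_concentration"].iloc[0] == pytest.approx(s.total_concentration)
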