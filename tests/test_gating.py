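import dataclasses

import numpy as np
import pandas as pd
import pytest

from uroflow.compensation import apply_compensation
from uroflow.errors import ValidationError
from uroflow.gating import (
    CRYSTAL_METHODS,
    PRIMARY_CLASSES,
    GateConfig,
    calibrate_birefringence_threshold,
    classify_sample,
    classify_tags,
    detect_crystals,
    exclude_beads,
    gate_dna,
)
from uroflow.synthdata import generate_event_table


@pytest.fixture(scope="module")
def compensated(sample_table, spillover):
    return apply_compensation(sample_table, spillover)


# ---------------------------------------------------------------------------
# Bead exclusion
# ---------------------------------------------------------------------------


def test_bead_split_matches_truth_labels(compensated):
    particles, beads = exclude_beads(compensated, GateConfig())
    # heavy-tailed scatter lets a handful of particles stray into the gate
    assert (beads.data["truth_label"] == "Bead").mean() > 0.99
    assert (beads.data["truth_label"] == "Bead").sum() == (
        compensated.data["truth_label"] == "Bead"
    ).sum()  # every true bead is caught
    assert len(particles) + len(beads) == len(compensated)
    true_beads = (compensated.data["truth_label"] == "Bead").sum()
    # well-separated signatures: at most a handful of strays either way
    assert abs(len(beads) - true_beads) <= 0.001 * len(compensated)


def test_no_bead_signature_gives_empty_beads(sparse_table_factory):
    table = sparse_table_factory([{"bf_area": 50.0, "ssc_intensity": 100.0}] * 5)
    particles, beads = exclude_beads(table, GateConfig())
    assert len(beads) == 0 and len(particles) == 5


def test_empty_table_splits_into_empty_tables(sparse_table_factory):
    table = sparse_table_factory([])
    particles, beads = exclude_beads(table, GateConfig())
    assert len(particles) == 0 and len(beads) == 0


# ---------------------------------------------------------------------------
# DNA gate
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "intensity,max_pixel,is_dna",
    [
        (2e5, 500.0, True),  # above both published thresholds
        (0.0, 0.0, False),
        (9e4, 500.0, False),  # intensity below the 1e5 a.u. cut-off
        (2e5, 50.0, False),  # max pixel below the 100 a.u. cut-off
    ],
)
def test_dna_gate_thresholds(sparse_table_factory, intensity, max_pixel, is_dna):
    table = sparse_table_factory(
        [{"Hoechst": max_pixel, "Hoechst_intensity": intensity}]
    )
    dna, non_cells = gate_dna(table, GateConfig())
    assert (len(dna) == 1) == is_dna
    assert len(dna) + len(non_cells) == 1


def test_dna_subclass_bacteria_by_area(sparse_table_factory):
    table = sparse_table_factory(
        [
            {"bf_area": 2.0, "Hoechst": 500.0, "Hoechst_intensity": 2e5},
            {"bf_area": 150.0, "Hoechst": 500.0, "Hoechst_intensity": 2e5},
        ]
    )
    result = classify_sample(table, GateConfig())
    assert list(result.labels["dna_subclass"]) == ["bacteria", "cell"]


# ---------------------------------------------------------------------------
# Tag-dominance classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "signals,expected",
    [
        ({"LipidTox": 500.0, "Proteostat": 50.0, "Calcein": 20.0}, "Lipid"),
        ({"Proteostat": 500.0}, "Protein"),
        ({"LipidTox": 500.0, "Proteostat": 500.0}, "LipidProtein"),
        ({"LipidTox": 99.0, "Proteostat": 99.0, "Calcein": 99.0}, "Unidentified"),
        ({"Calcein": 500.0, "LipidTox": 500.0}, "Calcium"),  # Calcein precedence
        ({"Calcein": 500.0, "LipidTox": 500.0, "Proteostat": 500.0}, "Calcium"),
    ],
)
def test_tag_dominance_classes(sparse_table_factory, signals, expected):
    table = sparse_table_factory([signals])
    assert classify_tags(table, GateConfig()).iloc[0] == expected


def test_exactly_one_primary_class_per_event(compensated):
    labels = classify_tags(compensated, GateConfig())
    assert labels.isin(set(PRIMARY_CLASSES) - {"DNA"}).all()


# ---------------------------------------------------------------------------
# Crystal detection
# ---------------------------------------------------------------------------


def test_only_birefringence_crystal_definition(sparse_table_factory):
    cfg = GateConfig()
    table = sparse_table_factory(
        [
            # bright birefringence, untagged -> crystal
            {"Birefringence": 500.0, "Birefringence_intensity": 5e3},
            # bright birefringence but Hoechst-tagged -> not a crystal
            {"Birefringence": 500.0, "Birefringence_intensity": 5e3,
             "Hoechst": 500.0},
            # no birefringence at all
            {},
        ]
    )
    flags = detect_crystals(table, "OnlyBirefringence", cfg)
    assert list(flags) == [True, False, False]


def test_no_birefringence_no_flag_under_any_method(sparse_table_factory):
    table = sparse_table_factory([{"Calcein": 500.0, "bf_area": 100.0}])
    for method in CRYSTAL_METHODS:
        assert not detect_crystals(table, method, GateConfig()).any()


def test_by_area_requires_large_object(sparse_table_factory):
    cfg = GateConfig()
    table = sparse_table_factory(
        [
            {"Birefringence": 500.0, "bf_area": 30.0},
            {"Birefringence": 500.0, "bf_area": 1.0},
        ]
    )
    assert list(detect_crystals(table, "ByArea", cfg)) == [True, False]


def test_by_calcein_requires_calcein_signal(sparse_table_factory):
    cfg = GateConfig()
    table = sparse_table_factory(
        [
            {"Birefringence": 500.0, "Calcein": 300.0},
            {"Birefringence": 500.0, "Calcein": 10.0},
        ]
    )
    assert list(detect_crystals(table, "ByCalcein", cfg)) == [True, False]


def test_unknown_crystal_method_rejected(sparse_table_factory):
    with pytest.raises(ValidationError):
        detect_crystals(sparse_table_factory([{}]), "ByMagic", GateConfig())


# ---------------------------------------------------------------------------
# Full hierarchy
# ---------------------------------------------------------------------------


def test_class_counts_within_binomial_bounds(compensated):
    """On well-separated synthetic data the recovered per-class counts sit
    within 3 binomial standard deviations of the generated truth."""
    result = classify_sample(compensated, GateConfig())
    truth = (
        compensated.data["truth_label"]
        .replace({"DNA_cell": "DNA", "DNA_bacteria": "DNA", "Crystal": "Calcium"})
        .value_counts()
    )
    n = int(truth.drop("Bead", errors="ignore").sum())
    for cls in PRIMARY_CLASSES:
        expected = int(truth.get(cls, 0))
        p = expected / n
        tol = 3 * np.sqrt(n * p * (1 - p)) + 1
        assert abs(result.counts[cls] - expected) <= tol, cls


def test_partition_exhaustive_and_disjoint(compensated):
    result = classify_sample(compensated, GateConfig())
    non_bead = result.labels.loc[~result.labels["is_bead"]]
    assert non_bead["primary_class"].isin(PRIMARY_CLASSES).all()
    assert sum(result.counts.values()) == len(non_bead)
    assert result.labels["is_bead"].sum() == result.n_beads


def test_beads_only_table_all_counts_zero(sparse_table_factory):
    table = sparse_table_factory(
        [{"bf_area": 3.0, "ssc_intensity": 2e4}] * 10
    )
    result = classify_sample(table, GateConfig())
    assert sum(result.counts.values()) == 0
    assert result.n_beads == 10


def test_blank_sample_below_two_percent_of_urine(spillover):
    """A PBS-blank-style acquisition yields a particle count under 2% of a
    paired urine-style table."""
    urine = generate_event_table(n_events=20_000, seed=31, spillover=spillover)
    blank = generate_event_table(
        n_events=0, seed=31, spillover=spillover,
        bead_fraction=0.0, class_counts={"Unidentified": 60},
    )
    cfg = GateConfig()
    n_urine = sum(classify_sample(apply_compensation(urine, spillover), cfg).counts.values())
    n_blank = sum(classify_sample(apply_compensation(blank, spillover), cfg).counts.values())
    assert n_blank < 0.02 * n_urine


def test_identified_counts_monotone_in_tag_threshold(compensated):
    """Raising the tag max-pixel threshold never increases the DNA,
    Calcium or LipidProtein counts nor the total identified count (single
    tags can only inherit events from the mixture class)."""
    base = classify_sample(compensated, GateConfig()).counts
    raised = classify_sample(
        compensated, GateConfig(tag_maxpixel_min=400.0)
    ).counts
    identified = lambda c: sum(v for k, v in c.items() if k != "Unidentified")
    assert identified(raised) <= identified(base)
    for cls in ("DNA", "Calcium", "LipidProtein"):
        assert raised[cls] <= base[cls]


def test_classification_deterministic(compensated):
    r1 = classify_sample(compensated, GateConfig())
    r2 = classify_sample(compensated, GateConfig())
    pd.testing.assert_frame_equal(r1.labels, r2.labels)
    assert r1.counts == r2.counts


def test_size_window_drops_out_of_range_events(sparse_table_factory):
    table = sparse_table_factory(
        [{"bf_area": 0.01}, {"bf_area": 5000.0}, {"bf_area": 10.0}]
    )
    result = classify_sample(table, GateConfig())
    assert result.n_size_dropped == 2
    assert sum(result.counts.values()) == 1


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def test_gate_config_yaml_round_trip(tmp_path):
    cfg = GateConfig(tag_maxpixel_min=150.0, biref_high_min=321.0)
    path = cfg.to_yaml(tmp_path / "gates.yaml")
    assert GateConfig.from_yaml(path) == cfg


def test_gate_config_rejects_unknown_keys(tmp_path):
    path = tmp_path / "gates.yaml"
    path.write_text("tag_maxpixel_min: 100\nnonsense_threshold: 1\n")
    with pytest.raises(ValidationError):
        GateConfig.from_yaml(path)


def test_gate_config_validation():
    with pytest.raises(ValidationError):
        GateConfig(area_min=10.0, area_max=1.0)
    with pytest.raises(ValidationError):
        GateConfig(tag_maxpixel_min=-5.0)


def test_birefringence_calibration_from_blank(sparse_table_factory):
    rows = [{"Birefringence": float(v), "Birefringence_intensity": float(v) * 10}
            for v in range(1, 1001)]
    blank = sparse_table_factory(rows)
    thr = calibrate_birefringence_threshold(blank, quantile=0.999)
    assert 990.0 <= thr <= 1000.0
    cfg = dataclasses.replace(GateConfig(), biref_high_min=thr)
    assert cfg.biref_high_min == thr
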