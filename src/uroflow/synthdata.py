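"""Synthetic imaging-flow-cytometry event tables and cohorts with ground truth.

The generator emulates the statistical structure of a two-visit,
three-day urine cohort of 18 healthy adults (9 female / 9 male, three per
gender in each of three age bands), measured twice daily (first-in-morning
and late-morning), i.e. 108 sample analyses, with a subset re-measured as
technical replicates.

Event features are drawn class-by-class from log-normal distributions:

* areas with medians set to the published per-class mean areas (lipids
  7.0 µm², proteins 10.4, lipid-proteins 10.7, calcium-tagged 9.3, DNA
  207, unidentified sub-µm);
* per-channel max pixels with a bright (≫100 a.u.) scale for the class's
  own tags and a dim background elsewhere, and intensities as a positive
  multiple of the max pixel so ``max_pixel ≤ intensity`` holds by
  construction;
* true per-dye signals forward-mixed through a known spillover matrix
  (``x = Sᵀ·y``), so the compensation stage has real work to undo.

Cohort structure: each sample draws a latent total concentration around
226 × 10³ particles/mL with ~30 % between-sample variability; replicate
measurements re-draw around the latent value so the mean absolute
relative difference between technical replicates is ~30 %.  Built-in
effects mirror the study's qualitative findings: bacteria appear only in
female samples, the late-morning lipid fraction doubles relative to
first-in-morning, rare samples carry birefringent crystals, and an
optional outlier participant runs several-fold above the cohort.

All randomness flows from one seed through named substreams, so any
single sample is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compensation import SpilloverMatrix
from .errors import ValidationError
from .io import (
    CHANNELS,
    EventTable,
    SampleRecord,
    intensity_column,
    max_pixel_column,
)

# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ChannelSignal:
    """Log-normal max-pixel scale plus intensity multiple for one channel.

    ``max_pixel ~ LogNormal(median=mp_median, sigma=mp_sigma)`` and
    ``intensity = max_pixel * (1 + LogNormal(median=factor_median,
    sigma=factor_sigma))`` — the factor is (roughly) the number of
    contributing pixels, keeping intensity strictly above max pixel.
    """

    mp_median: float
    mp_sigma: float
    factor_median: float
    factor_sigma: float


#: Dim, unstained background; comfortably below the 100 a.u. cut-off.
BACKGROUND = ChannelSignal(3.0, 0.8, 2.0, 0.5)
#: Birefringence background of non-crystalline material is darker still.
BIREF_BACKGROUND = ChannelSignal(1.0, 0.6, 1.0, 0.5)
#: Bright, tag-positive signal; comfortably above the 100 a.u. cut-off.
POSITIVE_TAG = ChannelSignal(1500.0, 0.6, 8.0, 0.5)
#: Hoechst signal of nucleated material; intensity median ~10⁶ a.u.
DNA_HOECHST = ChannelSignal(2000.0, 0.6, 500.0, 0.5)
BACTERIA_HOECHST = ChannelSignal(3000.0, 0.6, 330.0, 0.5)
#: Strong birefringence of crystalline particles.
CRYSTAL_BIREF = ChannelSignal(5000.0, 0.4, 30.0, 0.5)


def _default_signals() -> dict[str, ChannelSignal]:
    sig = {ch: BACKGROUND for ch in CHANNELS}
    sig["Birefringence"] = BIREF_BACKGROUND
    return sig


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """One generated particle class."""

    name: str
    fraction: float
    area_median: float  # µm²
    area_sigma: float  # log-sd
    signals: Mapping[str, ChannelSignal]
    ssc_median: float = 150.0
    ssc_sigma: float = 0.9

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValidationError("population fraction must be >= 0")
        if self.area_median <= 0:
            raise ValidationError("area median must be > 0")


def _pop(name, fraction, area_median, area_sigma, **bright) -> PopulationSpec:
    signals = _default_signals()
    signals.update(bright)
    return PopulationSpec(name, fraction, area_median, area_sigma, signals)


def default_populations(
    lipid: float = 0.06,
    protein: float = 0.13,
    lipid_protein: float = 0.23,
    calcium: float = 0.02,
    dna_cell: float = 0.01,
    dna_bacteria: float = 0.0,
    crystal: float = 0.0,
) -> list[PopulationSpec]:
    """Class mix for one sample; the unidentified class absorbs the rest.

    Default fractions follow the cohort-average composition (identified
    fraction 0.45 of ~226 × 10³ particles/mL).
    """
    identified = lipid + protein + lipid_protein + calcium + dna_cell + dna_bacteria + crystal
    if identified > 1:
        raise ValidationError("class fractions exceed 1")
    pops = [
        _pop("Lipid", lipid, 7.0, 0.6, LipidTox=POSITIVE_TAG),
        _pop("Protein", protein, 10.4, 0.6, Proteostat=POSITIVE_TAG),
        _pop("LipidProtein", lipid_protein, 10.7, 0.6,
             LipidTox=POSITIVE_TAG, Proteostat=POSITIVE_TAG),
        _pop("Calcium", calcium, 9.3, 0.6, Calcein=POSITIVE_TAG),
        _pop("DNA_cell", dna_cell, 207.0, 0.7, Hoechst=DNA_HOECHST),
        _pop("DNA_bacteria", dna_bacteria, 2.0, 0.4, Hoechst=BACTERIA_HOECHST),
        _pop("Crystal", crystal, 30.0, 0.3,
             Birefringence=CRYSTAL_BIREF,
             Calcein=ChannelSignal(400.0, 0.5, 6.0, 0.5)),
        _pop("Unidentified", 1.0 - identified, 0.5, 0.4),
    ]
    return [p for p in pops if p.fraction > 0]


#: Calibration beads: small, monodisperse, very high side scatter.
BEAD_POPULATION = PopulationSpec(
    "Bead", 0.0, 3.0, 0.1, _default_signals(), ssc_median=20000.0, ssc_sigma=0.15
)

#: Spillover used for forward mixing unless the caller supplies one.
DEFAULT_SPILLOVER_COEFFS = {
    ("Hoechst", "Calcein"): 0.04,
    ("Calcein", "Hoechst"): 0.02,
    ("Calcein", "LipidTox"): 0.06,
    ("LipidTox", "Proteostat"): 0.08,
    ("Proteostat", "LipidTox"): 0.05,
}


def default_spillover() -> SpilloverMatrix:
    n = len(CHANNELS)
    S = np.eye(n)
    idx = {c: i for i, c in enumerate(CHANNELS)}
    for (src, dst), coef in DEFAULT_SPILLOVER_COEFFS.items():
        S[idx[src], idx[dst]] = coef
    return SpilloverMatrix(S, CHANNELS)


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, sigma, size=n))


def _draw_population(rng: np.random.Generator, pop: PopulationSpec, n: int) -> pd.DataFrame:
    """True (pre-mixing) features for ``n`` events of one class."""
    data: dict[str, np.ndarray] = {
        "bf_area": _lognormal(rng, pop.area_median, pop.area_sigma, n),
        "ssc_intensity": _lognormal(rng, pop.ssc_median, pop.ssc_sigma, n),
    }
    for ch in CHANNELS:
        sig = pop.signals[ch]
        mp = _lognormal(rng, sig.mp_median, sig.mp_sigma, n)
        factor = _lognormal(rng, sig.factor_median, sig.factor_sigma, n)
        data[max_pixel_column(ch)] = mp
        data[intensity_column(ch)] = mp * (1.0 + factor)
    df = pd.DataFrame(data)
    df["truth_label"] = pop.name
    return df


def _forward_mix(df: pd.DataFrame, spillover: SpilloverMatrix) -> pd.DataFrame:
    """Replace true per-dye signals with detected (mixed) signals in place.

    Detected intensities are ``x = Sᵀ·y`` (i.e. ``X = Y·S`` row-wise); max
    pixels scale by the same per-event per-channel ratio, which keeps the
    compensation stage an exact inverse.
    """
    icols = [intensity_column(c) for c in CHANNELS]
    mcols = [max_pixel_column(c) for c in CHANNELS]
    Y = df[icols].to_numpy(dtype=float)
    X = Y @ spillover.matrix
    ratio = np.divide(X, Y, out=np.ones_like(X), where=Y > 0)
    df[icols] = X
    df[mcols] = df[mcols].to_numpy(dtype=float) * ratio
    return df


def generate_event_table(
    populations: Sequence[PopulationSpec] | None = None,
    n_events: int = 10_000,
    seed: int | np.random.Generator = 0,
    *,
    spillover: SpilloverMatrix | None = None,
    bead_fraction: float = 0.02,
    acquisition_volume_mL: float = 1.0,
    class_counts: Mapping[str, int] | None = None,
) -> EventTable:
    """Generate one sample's event table with per-event truth labels.

    Without ``class_counts``, per-class counts are a multinomial draw of
    ``n_events`` over the population fractions (which must sum to 1);
    with it, the given counts are drawn exactly.  Bead events
    (``bead_fraction`` of ``n_events``, rounded) are appended and labeled
    ``Bead``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    populations = list(populations) if populations is not None else default_populations()
    if n_events < 0:
        raise ValidationError("n_events must be >= 0")
    if class_counts is None:
        total_fraction = sum(p.fraction for p in populations)
        if not math.isclose(total_fraction, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(
                f"population fractions sum to {total_fraction}, expected 1"
            )
        counts = rng.multinomial(n_events, [p.fraction for p in populations]) if n_events else np.zeros(len(populations), dtype=int)
        class_counts = {p.name: int(c) for p, c in zip(populations, counts)}
    frames = []
    for pop in populations:
        n = int(class_counts.get(pop.name, 0))
        if n > 0:
            frames.append(_draw_population(rng, pop, n))
    n_beads = int(round(bead_fraction * n_events))
    if n_beads > 0:
        frames.append(_draw_population(rng, BEAD_POPULATION, n_beads))
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31 - 1))).reset_index(drop=True)
    else:
        df = _draw_population(rng, BEAD_POPULATION, 0)
    df = _forward_mix(df, spillover or default_spillover())
    df.insert(0, "event_id", np.arange(len(df)))
    return EventTable(df, CHANNELS, acquisition_volume_mL)


def generate_controls(
    seed: int = 0,
    spillover: SpilloverMatrix | None = None,
    n_events: int = 1000,
) -> dict[str, EventTable]:
    """Single-stain control tables, one per channel, forward-mixed.

    Controls carry true signal only in their stained channel, so the
    median-ratio spillover estimator recovers the mixing matrix exactly.
    """
    spillover = spillover or default_spillover()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    controls: dict[str, EventTable] = {}
    for ch in CHANNELS:
        signals = {c: ChannelSignal(0.0, 0.0, 0.0, 0.0) for c in CHANNELS}
        signals[ch] = POSITIVE_TAG
        data: dict[str, np.ndarray] = {
            "bf_area": _lognormal(rng, 5.0, 0.5, n_events),
            "ssc_intensity": _lognormal(rng, 150.0, 0.9, n_events),
        }
        for c in CHANNELS:
            sig = signals[c]
            if sig.mp_median > 0:
                mp = _lognormal(rng, sig.mp_median, sig.mp_sigma, n_events)
                factor = _lognormal(rng, sig.factor_median, sig.factor_sigma, n_events)
            else:
                mp = np.zeros(n_events)
                factor = np.zeros(n_events)
            data[max_pixel_column(c)] = mp
            data[intensity_column(c)] = mp * (1.0 + factor)
        df = pd.DataFrame(data)
        df["truth_label"] = ch
        df = _forward_mix(df, spillover)
        controls[ch] = EventTable(df, CHANNELS, 1.0)
    return controls


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SyntheticCohortSpec:
    """Ground-truth cohort structure and effect switches.

    The defaults reproduce the study design: 3 participants per gender per
    age band (18 total), two collection times on each of three days (108
    samples), 74 of them measured twice; total concentration around
    226 × 10³ particles/mL of urine with ~30 % between-sample and ~30 %
    replicate variability; late-morning lipid fraction doubled; bacteria
    only in female samples; two crystal-positive samples from one
    participant; optional high-concentration outlier participant.
    """

    participants_per_group: int = 3
    days: int = 3
    events_per_sample: int = 100_000
    base_total_concentration: float = 226e3  # particles/mL urine
    concentration_factor: float = 100.0
    between_sample_cv: float = 0.30
    replicate_variability: float = 0.30  # target mean |c1-c2|/mean
    n_replicated_samples: int = 74
    bead_fraction: float = 0.02
    # class composition (fractions of total particles)
    protein_fraction: float = 0.13
    lipid_protein_fraction: float = 0.23
    calcium_fraction: float = 0.02
    fim_lipid_fraction: float = 0.04
    lm_lipid_multiplier: float = 2.0
    dna_fraction_male: float = 0.0005
    dna_fraction_female: float = 0.0125
    female_bacteria: bool = True
    bacteria_share_of_female_dna: float = 0.9
    crystal_positive_samples: int = 2
    crystal_fraction: float = 0.005
    outlier_participant: bool = False
    outlier_multiplier: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participants_per_group < 1 or self.days < 1:
            raise ValidationError("participants_per_group and days must be >= 1")
        if self.events_per_sample < 0:
            raise ValidationError("events_per_sample must be >= 0")
        if self.lm_lipid_multiplier <= 0 or self.outlier_multiplier <= 0:
            raise ValidationError("multipliers must be > 0")
        n_samples = self.n_samples
        if not 0 <= self.n_replicated_samples <= n_samples:
            raise ValidationError(
                f"n_replicated_samples must be in [0, {n_samples}]"
            )

    @property
    def n_participants(self) -> int:
        return self.participants_per_group * 2 * 3

    @property
    def n_samples(self) -> int:
        return self.n_participants * 2 * self.days

    @property
    def acquisition_volume_mL(self) -> float:
        """Acquired volume chosen so a nominal sample yields
        ``events_per_sample`` particle events."""
        return self.events_per_sample / (
            self.base_total_concentration * self.concentration_factor
        )

    @property
    def replicate_sigma(self) -> float:
        """Log-sd of the replicate-level draw.

        For two log-normal replicates around a common latent value,
        ``E|c1 − c2| / mean ≈ 2σ/√π``; inverting gives σ for the target
        mean replicate variability.
        """
        return self.replicate_variability * math.sqrt(math.pi) / 2.0


@dataclasses.dataclass
class CohortData:
    records: list[SampleRecord]
    tables: dict[tuple[str, int], EventTable]  # (sample_id, replicate_index)
    truth: pd.DataFrame  # latent per-measurement class concentrations
    spillover: SpilloverMatrix
    spec: SyntheticCohortSpec


_AGE_GROUPS = ("younger", "middle", "older")


def _sample_rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def generate_cohort(spec: SyntheticCohortSpec | None = None) -> CohortData:
    """Generate the full synthetic cohort: manifest, event tables, truth.

    The truth table has one row per measurement (sample × replicate) with
    the latent per-class concentrations the event counts were drawn from
    (Poisson counts at ``concentration × volume × factor``).
    """
    spec = spec or SyntheticCohortSpec()
    spillover = default_spillover()
    records: list[SampleRecord] = []
    tables: dict[tuple[str, int], EventTable] = {}
    truth_rows: list[dict] = []

    participants = []
    pid = 0
    for age_group in _AGE_GROUPS:
        for gender in ("female", "male"):
            for _ in range(spec.participants_per_group):
                pid += 1
                participants.append((f"P{pid:02d}", gender, age_group))

    # which samples get a second replicate / crystals — one master substream
    master = _sample_rng(spec.seed, 0)
    n_samples = spec.n_samples
    replicated = set(
        master.choice(n_samples, size=spec.n_replicated_samples, replace=False)
    )
    # crystals: pick one female participant, first `crystal_positive_samples`
    # of her measurements
    female_ids = [p[0] for p in participants if p[1] == "female"]
    crystal_pid = female_ids[int(master.integers(len(female_ids)))]

    outlier_list = []
    if spec.outlier_participant:
        outlier_list.append(("O1", "female", "older"))

    sample_index = 0
    crystal_assigned = 0
    for part_ordinal, (participant_id, gender, age_group) in enumerate(
        participants + outlier_list
    ):
        is_outlier = participant_id.startswith("O")
        # participant-level baseline (part of the between-sample spread)
        prng = _sample_rng(spec.seed, 1, part_ordinal)
        sigma_b = math.sqrt(math.log(1.0 + spec.between_sample_cv**2))
        part_level = math.exp(prng.normal(0.0, sigma_b / 2.0))
        for day in range(1, spec.days + 1):
            for time in ("FIM", "LM"):
                sample_id = f"{participant_id}-D{day}-{time}"
                lipid = spec.fim_lipid_fraction * (
                    spec.lm_lipid_multiplier if time == "LM" else 1.0
                )
                dna = (
                    spec.dna_fraction_female
                    if gender == "female"
                    else spec.dna_fraction_male
                )
                bact_share = (
                    spec.bacteria_share_of_female_dna
                    if (gender == "female" and spec.female_bacteria)
                    else 0.0
                )
                crystal = 0.0
                if (
                    participant_id == crystal_pid
                    and crystal_assigned < spec.crystal_positive_samples
                ):
                    crystal = spec.crystal_fraction
                    crystal_assigned += 1
                fractions = {
                    "Lipid": lipid,
                    "Protein": spec.protein_fraction,
                    "LipidProtein": spec.lipid_protein_fraction,
                    "Calcium": spec.calcium_fraction,
                    "DNA_cell": dna * (1.0 - bact_share),
                    "DNA_bacteria": dna * bact_share,
                    "Crystal": crystal,
                }
                fractions["Unidentified"] = 1.0 - sum(fractions.values())

                srng = _sample_rng(spec.seed, 2, sample_index)
                latent_total = (
                    spec.base_total_concentration
                    * part_level
                    * math.exp(srng.normal(0.0, sigma_b / 2.0))
                )
                if is_outlier:
                    latent_total *= spec.outlier_multiplier
                n_reps = 2 if (sample_index in replicated and not is_outlier) else 1
                for rep in range(1, n_reps + 1):
                    rrng = _sample_rng(spec.seed, 3, sample_index, rep)
                    rep_total = latent_total * math.exp(
                        rrng.normal(0.0, spec.replicate_sigma)
                    )
                    class_conc = {
                        name: rep_total * frac for name, frac in fractions.items()
                    }
                    lam = {
                        name: conc
                        * spec.acquisition_volume_mL
                        * spec.concentration_factor
                        for name, conc in class_conc.items()
                    }
                    counts = {name: int(rrng.poisson(l)) for name, l in lam.items()}
                    pops = _catalogue()
                    table = generate_event_table(
                        pops,
                        n_events=spec.events_per_sample,
                        seed=rrng,
                        spillover=spillover,
                        bead_fraction=spec.bead_fraction,
                        acquisition_volume_mL=spec.acquisition_volume_mL,
                        class_counts=counts,
                    )
                    if rep == 1:
                        records.append(
                            SampleRecord(
                                sample_id=sample_id,
                                participant_id=participant_id,
                                gender=gender,
                                age_group=age_group,
                                collection_time=time,
                                day_index=day,
                                replicate_index=1,
                                concentration_factor=spec.concentration_factor,
                                outlier_flag=is_outlier,
                            )
                        )
                    tables[(sample_id, rep)] = table
                    row = {
                        "sample_id": sample_id,
                        "replicate_index": rep,
                        "participant_id": participant_id,
                        "gender": gender,
                        "age_group": age_group,
                        "collection_time": time,
                        "day_index": day,
                        "outlier_flag": is_outlier,
                        "true_total_concentration": rep_total,
                        "latent_sample_concentration": latent_total,
                    }
                    for name, conc in class_conc.items():
                        row[f"true_conc_{name}"] = conc
                    truth_rows.append(row)
                sample_index += 1

    truth = pd.DataFrame(truth_rows)
    # fold the generator's DNA sub-labels into the analysis class; crystals
    # stay separate (their gated primary class is Calcium, so consumers add
    # true_conc_Crystal to true_conc_Calcium when comparing)
    truth["true_conc_DNA"] = truth["true_conc_DNA_cell"] + truth["true_conc_DNA_bacteria"]
    return CohortData(records, tables, truth, spillover, spec)


def _catalogue() -> list[PopulationSpec]:
    """All population specs (fractions unused when counts are explicit)."""
    return [
        _pop("Lipid", 0.0, 7.0, 0.6, LipidTox=POSITIVE_TAG),
        _pop("Protein", 0.0, 10.4, 0.6, Proteostat=POSITIVE_TAG),
        _pop("LipidProtein", 0.0, 10.7, 0.6,
             LipidTox=POSITIVE_TAG, Proteostat=POSITIVE_TAG),
        _pop("Calcium", 0.0, 9.3, 0.6, Calcein=POSITIVE_TAG),
        _pop("DNA_cell", 0.0, 207.0, 0.7, Hoechst=DNA_HOECHST),
        _pop("DNA_bacteria", 0.0, 2.0, 0.4, Hoechst=BACTERIA_HOECHST),
        _pop("Crystal", 0.0, 30.0, 0.3,
             Birefringence=CRYSTAL_BIREF,
             Calcein=ChannelSignal(400.0, 0.5, 6.0, 0.5)),
        _pop("Unidentified", 0.0, 0.5, 0.4),
    ]
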