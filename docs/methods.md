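# Methods

## The measurement model

Each imaging-flow-cytometry event is a particle described by a
bright-field projected area (µm²), a side-scatter intensity (a.u.) and,
per fluorescence channel *c* ∈ {Hoechst, Calcein, LipidTox, Proteostat,
Birefringence}, a total intensity (summed fluorescence over the particle
image) and a max pixel (brightest single pixel). Max pixel is one pixel
of the summed signal, so `max_pixel[c] ≤ intensity[c]` is a structural
invariant enforced at I/O boundaries.

Detected intensities mix linearly across channels: with spillover matrix
*S* (rows = source dye, columns = detector, unit diagonal, off-diagonals
in [0, 1)), the detected vector is *x = Sᵀ·y* for true per-dye signal
*y*. Compensation inverts this per event.

### Spillover estimation

Entry *S[i, j]* is the **median of per-event ratios** `x_j / x_i` among
events of the channel-*i* single-stain control that are positive in
channel *i*. The median is a robust slope-through-the-origin estimator
that is parameter-free and resistant to the heavy right tails of
cytometry intensities; ordinary least squares would be dominated by the
few brightest events. Positivity defaults to intensity > 100 a.u. and
should in practice be calibrated from an unstained region (e.g. its 95th
percentile). A control with fewer than `min_positive_events` (default
10) positives is rejected, as is any estimated off-diagonal ≥ 1
(non-physical).

### Compensation of max pixels

Max pixel is a nonlinear image feature and cannot be unmixed
independently without breaking its ordering against intensity. Each
event's max pixel is therefore scaled per channel by the same correction
ratio `y_c / x_c` the unmixing applied to that channel's intensity.
Negative compensated values (possible when the matrix over-corrects a
dim channel) are clamped to 0, and max pixels are re-capped at the
compensated intensity, because every downstream gate assumes
non-negative signals. Areas and side scatter are never touched.

## The gating hierarchy

All gates are axis-aligned thresholds (`GateConfig`), serializable to
YAML. Hand-drawn two-dimensional regions in vendor software are not
reproducible; thresholds are, and the two published numeric anchors —
tag max pixel 100 a.u. and Hoechst intensity 10⁵ a.u. — are kept as
defaults. Thresholds are applied to **compensated** signals.

| threshold | default | units | rationale |
|---|---|---|---|
| `area_min` / `area_max` | 0.1 / 4900 | µm² | instrument detection window: 0.33 µm pixel resolution, 70 µm pre-filter mesh |
| `bead_area_max`, `bead_ssc_min` | 15, 5000 | µm², a.u. | calibration beads are small with very high side scatter; instrument-specific |
| `hoechst_intensity_min` | 10⁵ | a.u. | published DNA-identification cut-off |
| `tag_maxpixel_min` | 100 | a.u. | published tag-identification cut-off |
| `bacteria_area_max` | 20 | µm² | splits small bacteria from larger cells inside the DNA gate; qualitative, no published number |
| `biref_high_min` | 300 | a.u. | "high birefringence"; better calibrated per instrument as the 99.9th percentile of a blank run (`calibrate_birefringence_threshold`) |
| `biref_area_min` | 15 | µm² | crystal-by-area detector: large birefringent objects |
| `biref_calcein_min` | 100 | a.u. | crystal-by-Calcein detector: calcium-bearing crystals |
| `crystal_other_tag_max` | 100 | a.u. | "minimal signal" in LipidTox/Proteostat/Hoechst for the only-birefringence detector |

Stages, in order: (1) events outside `[area_min, area_max]` are dropped
with a logged count; (2) beads are removed by the area × side-scatter
signature; (3) events above both Hoechst thresholds are DNA particles,
with an area cut separating bacteria from cells; (4) remaining non-cell
events are classified from tag max pixels with the precedence
**Calcein → LipidTox∧Proteostat → single tag → Unidentified**. Calcein
wins ties because calcium-tagged particles are reported independently of
their lipid/protein content, and the published subpopulation
concentrations are disjoint (they sum to the identified total), so
multi-positive events must resolve deterministically.

Crystal flags are **annotations, not primary classes**: a flagged event
keeps its primary class for concentration accounting, and the three
detectors (ByArea, ByCalcein, OnlyBirefringence) are reported per
sample. Only the only-birefringence detector — high birefringence
intensity with all of LipidTox, Proteostat and Hoechst at background —
is treated as a true crystal gate; the other two are retained as the
comparative methods they are. Sample-level crystal presence is defined
as ≥ 3 only-birefringence events, which at 10⁴–10⁵ events per sample is
far above the background false-positive rate of the default thresholds.

A note on monotonicity: raising `tag_maxpixel_min` can only shrink the
total identified count, the DNA, Calcium and LipidProtein counts. The
single-tag Lipid/Protein counts are *not* individually monotone, because
an event leaving the two-tag mixture class when one tag drops below
threshold re-enters a single-tag class. The tests assert the monotone
statements only.

## Quantification

* concentration = `count / (acquisition_volume_mL × concentration_factor)`,
  in particles per mL of original urine. The acquired volume is not a
  derivable quantity and is carried as table metadata (sidecar file for
  CSV, a custom keyword for FCS).
* equivalent diameter = `2·√(A/π)` (µm), reported at 1 decimal place in
  tables. For the published mean areas 4.3 / 7.0 / 9.3 / 207 µm² this
  gives 2.3 / 3.0 / 3.4 / 16.2 µm.
* identified fraction = 1 − (Unidentified / non-bead events).
* replicate merging: arithmetic mean of concentrations and mean areas;
  replicate variability = `|c₁ − c₂| / mean(c₁, c₂)` on total
  concentration. The variability statistic is a definition of this
  package (the ~30 % figure it targets is reported without a formula);
  the synthetic generator is calibrated to the same statistic.
* daily load = total concentration × daily urine volume (default
  1,400 mL, the midpoint of the normal 800–2,000 mL range).
* per-class mean areas are computed per sample and then averaged across
  samples (not pooled over events), matching how the cohort tables are
  built from per-sample statistics.

## Cohort statistics

Two-level factors (collection time, gender) use the **Welch** two-sided
t-test — the equal-variance assumption is not defensible given the
visibly unequal group spreads — and the three age groups use classical
one-way ANOVA, both at α = 0.05 with no multiple-testing correction
(per-test reporting; a Benjamini–Hochberg switch exists for users who
want FDR control). Replicates are merged before testing; technical
repeats are never treated as independent observations. Day-level samples
within a participant are likewise *not* averaged before testing — each
of the 108 samples enters as one observation, a documented choice rather
than an inference about the original analysis. Outlier-flagged
participants are excluded from baseline tables and reported separately.
Degenerate inputs (all-constant groups with equal means) return
statistic 0, p = 1; all-constant groups with unequal means raise a
degenerate-data error rather than fabricating an infinite statistic.

## The synthetic cohort

The generator emulates the *statistical* structure of the study data,
not its imagery:

* design: 3 participants per gender × age band (18 total), 2 collection
  times × 3 days = 108 samples, 74 randomly chosen samples measured
  twice, ~2 % calibration-bead events per table;
* composition: class fractions Lipid 0.06 (0.04 first-in-morning, 0.08
  late-morning), Protein 0.13, LipidProtein 0.23, Calcium 0.02, DNA
  0.0005 (male) / 0.0125 (female, 90 % bacteria), remainder
  unidentified — identified fraction ≈ 0.45 of a total around
  226 × 10³ particles/mL;
* sizes: per-class log-normal areas with medians at the published class
  means (7.0, 10.4, 10.7, 9.3, 207 µm²; unidentified 0.5 µm², i.e.
  sub-µm diameters) and log-sd 0.4–0.7. Because the log-normal mean
  exceeds its median, recovered per-sample *mean* areas sit somewhat
  above these medians; the generator is calibrated on concentrations,
  not on matching the published mean-area table exactly;
* signals: bright tags at max-pixel median 1,500 a.u. (log-sd 0.6),
  backgrounds at ~3 a.u., DNA Hoechst intensity median ~10⁶ a.u. —
  placed so the 100 / 10⁵ a.u. gates sit many log-sd from both sides
  (misclassification ~10⁻⁵ at defaults). Intensities are
  `max_pixel × (1 + log-normal factor)`, keeping the structural
  invariant by construction;
* variability: latent per-sample totals are log-normal around the
  baseline with cv 0.30 (split between a participant level and a sample
  level); replicates re-draw with log-sd `0.30·√π/2 ≈ 0.266`, which
  makes the expected `|c₁−c₂|/mean` ≈ 0.30;
* events: per-class Poisson counts at `concentration × volume × factor`;
  the acquired volume is set so a nominal sample yields
  `events_per_sample` events (10⁵ by default);
* effects: late-morning lipid fraction ×2; bacteria only in female
  samples; two crystal-positive samples from one female participant
  (0.5 % crystal events, strongly birefringent, Calcein-positive,
  otherwise untagged); optional ×4 outlier participant "O1" excluded
  from baselines;
* all randomness flows from one seed through named `SeedSequence`
  substreams (participant, sample, replicate), so any one sample is
  reproducible in isolation.

What it does **not** emulate — and hence what passing tests do not show
about real data: pixel images, masks, focus artifacts and doublets;
autofluorescence and spectral overlap beyond a fixed linear spillover;
non-log-normal size tails; storage-time aggregation kinetics (the
late-preparation concentration drop is a scenario parameter, not a
model); correlations between class fraction and particle size within a
sample; any real biological covariance between factors. Clean threshold
recovery on synthetic data demonstrates correctness of the pipeline
arithmetic, not that axis-aligned thresholds match any particular
instrument's hand-drawn gates.

## Numerical and scale choices

* Unmixing uses `numpy.linalg.solve` on *Sᵀ*; a singular matrix raises a
  numeric error (exit code 4 in the CLI).
* FCS support covers the profile the package writes: FCS 3.0/3.1,
  list-mode, single dataset, 32-bit float, with truth labels carried as
  an integer-coded extra parameter. CSV is exact; FCS round-trips at
  float32 precision.
* Cohort-scale validation runs the full 108-sample design at a reduced
  10,000 events per sample (and 2,000 for the repeated effect-recovery
  runs); per-class recovery tolerances are 3 Monte-Carlo standard
  errors, so they scale correctly with the reduced event counts.
* Tie-breaks: gate comparisons are strict (`>`) for the published
  cut-offs ("higher than") and inclusive (`≥`) for the instrument-
  calibrated birefringence/bead thresholds; events exactly at a
  threshold are therefore handled deterministically.

## Known limitations

* The spillover estimator is a documented stand-in; vendor software
  computes its matrix by an unpublished method, and no claim of
  equivalence is made.
* Whether identification thresholds should apply to raw or compensated
  signals is ambiguous in the source material; this package applies them
  post-compensation.
* Bead, bacteria/cell and birefringence thresholds have no published
  values and default to values separable on the synthetic signature;
  real instruments require calibration (blank runs, bead controls).
* No mixed-effects modeling of repeated days within participant, no
  post-hoc ANOVA contrasts, no volumetric calibration from bead counts.
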