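# uroflow

Quantitative characterization of the particulate content of human urine
from imaging-flow-cytometry (IFC) event features.

Healthy urine carries hundreds of thousands of suspended particles per
millilitre in the 0.33–70 µm size range — lipid droplets, protein
aggregates, lipid–protein complexes, calcium-bearing particles, cells and
bacteria, and occasional birefringent crystals such as calcium oxalate.
An imaging flow cytometer records, for every particle, a bright-field
area, a side-scatter intensity, and per-channel fluorescence features for
a panel of tags (Hoechst for double-stranded DNA, Calcein for Ca²⁺,
LipidTox for lipids, Proteostat for protein aggregates) plus a
polarization-based birefringence channel. `uroflow` turns those per-event
feature tables into per-sample particle inventories and cohort-level
statistics:

* **compensation** — estimates the inter-channel spillover matrix *S*
  from single-stain controls (median per-event ratio among positive
  events) and solves the linear unmixing *Sᵀ·y = x* per event;
* **gating** — a reproducible, threshold-based version of the standard
  hierarchy: calibration-bead exclusion (area × side scatter), a DNA gate
  on Hoechst intensity (> 10⁵ a.u.) × max pixel (> 100 a.u.),
  tag-dominance classification of the remaining "non-cell" events into
  Calcium / Lipid / Protein / LipidProtein / Unidentified, and three
  complementary birefringence-based crystal detectors;
* **quantify** — concentrations in particles per mL of original urine
  (`count / (acquired volume × 100-fold concentration factor)`),
  per-class mean areas and circle-equivalent diameters
  (*d = 2·√(A/π)*), identified fraction, replicate merging with a
  `|c₁−c₂|/mean` variability metric, and the daily particle load
  (concentration × 1,400 mL);
* **stats** — Welch two-sided t-tests for time-of-day and gender, one-way
  ANOVA for age groups, subgroup cross-tables, mean ± SE group summaries
  at α = 0.05;
* **synthdata** — a seeded synthetic-cohort generator (18 participants,
  2 collection times × 3 days = 108 samples, ≥10⁵ events per sample, ~30 %
  replicate variability, bacteria only in female samples, late-morning
  lipid doubling, rare crystal-positive samples) that provides ground
  truth for every stage.

Event tables are read and written as CSV or FCS 3.0/3.1 (list-mode,
float data), with a configurable mapping from instrument channel labels
to semantic names.

## Worked example

```python
from uroflow import (GateConfig, SampleRecord, apply_compensation, classify_sample,
                     daily_load, equivalent_diameter, estimate_spillover,
                     summarize_sample)
from uroflow.synthdata import default_spillover, generate_controls, generate_event_table

spillover = default_spillover()
table = generate_event_table(n_events=100_000, seed=42, spillover=spillover,
                             acquisition_volume_mL=0.00442)
controls = generate_controls(seed=42, spillover=spillover)

S_hat = estimate_spillover(controls)             # from single-stain controls
compensated = apply_compensation(table, S_hat)   # per-event linear unmixing
result = classify_sample(compensated, GateConfig())
record = SampleRecord("P01-D1-FIM", "P01", "female", "younger", "FIM", 1, 1)
summary = summarize_sample(result, table, record)
```

Printed with the snippet at the end of this section, the run above yields:

```
events analysed      : 99989  (+2009 beads excluded)
total concentration  : 226 x 10^3 particles/mL
identified fraction  : 44.8%
  Lipid        :   13.3 x 10^3 /mL   mean area    8.3 um^2   d = 3.3 um
  Protein      :   29.3 x 10^3 /mL   mean area   12.4 um^2   d = 4.0 um
  LipidProtein :   51.9 x 10^3 /mL   mean area   12.8 um^2   d = 4.0 um
  Calcium      :    4.6 x 10^3 /mL   mean area   11.3 um^2   d = 3.8 um
  DNA          :    2.3 x 10^3 /mL   mean area  248.5 um^2   d = 17.8 um
daily load at 1400 mL: 317 x 10^6 particles/day
```

Reading the output: ~100k imaged events, minus the calibration beads,
convert to 226 × 10³ particles per mL of original urine at the 0.00442 mL
acquired volume and 100× preparation factor. About 45 % of particles are
identified by at least one tag; lipid–protein complexes are the largest
identified class, and DNA-containing particles (cells) are rare but an
order of magnitude larger in area than everything else. The daily load
extrapolates the concentration to a normal 1,400 mL 24-hour urine volume.

```python
print(f"events analysed      : {summary.event_count}  (+{result.n_beads} beads excluded)")
print(f"total concentration  : {summary.total_concentration/1e3:.0f} x 10^3 particles/mL")
print(f"identified fraction  : {summary.identified_fraction:.1%}")
for cls in ("Lipid", "Protein", "LipidProtein", "Calcium", "DNA"):
    c, a = summary.concentrations[cls], summary.mean_areas[cls]
    print(f"  {cls:13s}: {c/1e3:6.1f} x 10^3 /mL   mean area {a:6.1f} um^2"
          f"   d = {equivalent_diameter(a, 1):.1f} um")
print(f"daily load at 1400 mL: {daily_load(summary.total_concentration)/1e6:.0f}"
      " x 10^6 particles/day")
```

## Command line

The `uroflow` entry point chains the stages from one config file or runs
them individually:

```sh
uroflow run --out results --seed 1 --events-per-sample 10000
# or, composably:
uroflow simulate --out c --seed 1
uroflow gate      --in c --out g
uroflow summarize --in c --gated g --out s
uroflow stats     --in c --summaries s --out t
uroflow report    --in c --summaries s --stats t --out r
```

Exit codes: 0 success, 2 validation, 3 I/O, 4 numeric. Every output
directory receives a `run_log.json` with the package version and a hash
of the effective configuration.

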