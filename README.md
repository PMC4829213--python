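# traffiq

Simulation and single-cell quantification of retroviral mRNA
nuclear-export and trafficking time-lapse movies.

## The problem

Retroviral full-length genomic RNAs (gRNAs) leave the nucleus by one of
two dedicated export pathways, and live-cell imaging shows that the
pathway *pre-programs* the transcript's later behavior in the cytoplasm:

* **Rev/CRM1 (RRE-bearing transcripts).** Export is frequently an
  en-masse "burst": MS2-YFP-labeled transcripts accumulate in the nucleus
  until they saturate the free coat-protein pool, then evacuate in under
  an hour. In other cells the same construct shows a gradual
  min-to-max shift of the cytoplasmic:nuclear (C:N) intensity ratio over
  roughly nine hours.
* **NXF1/NXT1 (CTE-bearing transcripts).** Export is constitutive, and
  exported transcripts engage microtubules near the nuclear envelope,
  moving bidirectionally at motor-like speeds (~0.6 μm/s) with a net
  minus-end bias that clusters them at the centrosome / MTOC.
  Depolymerizing microtubules with nocodazole arrests transcripts at the
  nuclear membrane and abolishes the clustering.

The package provides, for researchers who quantify such movies:

1. **`scenarios`** — an agent-based simulator of single-cell gRNA
   trafficking (transcription, pool-limited MS2 labeling, burst/gradual/
   CTE export programs, microtubule runs, MTOC capture) plus reporter
   kinetics (Rev-mCherry onset, Gag-CFP accumulation, membrane VLP
   punctae), with a registry of named presets whose penetrances and
   kinetic parameters follow the published single-cell measurements.
2. **`render`** — a calibrated synthetic-microscopy renderer (Gaussian
   PSF, Poisson shot noise, Gaussian read noise, 16-bit camera) that
   turns ground-truth histories into multichannel OME-TIFF stacks.
3. **`measure` / `kinetics` / `phenotype` / `tracking`** — the
   measurement pipeline: nucleus/cell segmentation, background
   subtraction, compartment MFI, punctae detection and fold-enrichment,
   C:N trace analysis (onset detection, peak alignment, 10–90% transition
   duration, burst classification, VLP onset), endpoint phenotype scoring
   (nuclear/cytoplasmic/equal, MTOC targeting), and fast-mode
   single-particle tracking with MSD motion classification.
4. **`pipeline` / CLI** — end-to-end orchestration
   (`simulate → render → measure → analyze → score`, `track` in fast
   mode) with deterministic seeded reports.

Because every stage consumes only rendered images, the whole pipeline is
verifiable by parameter recovery: simulate a condition, render it, measure
it, and check that the recovered burst fractions, transition durations,
enrichment folds, onset times and speeds match what the simulator was told
to produce.

## Core quantities

* **C:N ratio** — cytoplasmic MFI ÷ nuclear MFI of the MS2-YFP signal,
  background-subtracted; the readout of export progress.
* **Transition duration** — `(t_last_cross(0.9) − t_first_cross(0.1)) / 0.8`
  of the min-max normalized C:N trace; a cell is a **burst** cell when its
  duration is under 1 h and its final C:N ≥ 1.5.
* **Punctae enrichment** — spot-disk MFI ÷ spot-free nucleoplasm MFI
  (disk radius 2·σ_PSF); nuclear transcripts read ≈2.8-fold.
* **MTOC targeting** — MFI in a 3 μm disk around the centrosome ÷ MFI of
  the remaining cytoplasm, called targeted at ≥3-fold.
* **MSD exponent α** — slope of log MSD vs log lag; ≥1.3 directed,
  ≤0.7 confined, else diffusive.

## Worked example

```python
from traffiq import RunConfig, run_experiment

report = run_experiment(RunConfig(scenario="RRE_Rev", n_cells=30, seed=1))
print(report["phenotype"]["cytoplasmic"])
print(report["export_classes"]["burst"])
print(report["transition"]["mean_duration_h"])
```

prints (seed 1, 30 cells):

```
{'mean': 0.8, 'sd': nan}
{'mean': 0.3333333333333333, 'sd': nan}
8.655581351191435
```

i.e. 80% of the 30 simulated Rev-supplied cells scored
cytoplasmic-dominant at the endpoint (the preset penetrance is 74.3%;
binomial noise at n=30 is ±8 points), a third of cells classified as
burst exporters from their measured C:N traces, and the mean measured
C:N min-to-max transition was ≈8.7 h against the 9.0 ± 3.4 h generative
program. The same pipeline runs from a shell:

```bash
traffiq run --scenario RRE_Rev --cells 30 --seed 1 --out report.json
traffiq repro burst-fraction --seed 1
```

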