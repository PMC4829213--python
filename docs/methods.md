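# Methods

This note documents the generative model, the optical model, the
measurement conventions and the numerical choices behind `traffiq`, in
enough detail to judge what a passing parameter-recovery run does and
does not demonstrate.

## Cell geometry

Each simulated cell is a star-convex adherent cell: a base radius drawn
from N(14, 1.5) μm perturbed by low-order cosine harmonics (≤5% of the
radius per harmonic), an axis-aligned elliptical nucleus with semi-axes
around 7.0 × 5.5 μm (jittered ±10%, shrunk if needed to stay well inside
the outline), 1–3 transcription sites placed in the nuclear interior, a
centrosome 2.5 μm outside the nuclear envelope (juxtanuclear by
construction), and 24 straight microtubule tracks radiating from the
centrosome to the cell boundary. Coordinates are micrometres with the
origin at the cell centre; rendering places the centre mid-field with a
0.325 μm pixel (20×-objective-like sampling) in the long mode and
0.065 μm (100×-like) in the fast mode.

## Transcription and MS2 labeling

Transcripts are born as a Poisson process at rate `k_tx` (default 10/h;
the nuclear-retention presets use 2.5/h so individual punctae remain
optically resolvable, matching the sparse punctae those conditions show).
Each transcript carries 24 MS2 stem-loops and can bind up to 48
fluorescent coat proteins from a finite nuclear pool (`ms2_pool_units`,
default 2545). The first `n_labeled_max` = 50 transcripts bind 48 coats
each; later transcripts find the pool exhausted and stay dark. The free
nuclear pool is therefore `Y_tot − 48 · (labeled transcripts born)`,
floored at zero — the pool-saturation reading of the burst phenotype.

The residual free pool after saturation (145 units) is deliberate: it
sets the asymptotic measured C:N ratio of a fully exported cell to
`c_end = s · 2400 / 145` where `s` is the cell's nucleus:cytoplasm area
ratio (≈0.17–0.36), i.e. C:N ≈ 2–5 — comfortably above the 1.5
cytoplasmic-dominant threshold for every geometry the generator draws,
while leaving a smooth nuclear signal whose shot noise does not destabilize
trace normalization.

## Export programs

Per cell, a scenario draws whether it exports at all (`frac_exporting`)
and whether it shows the hallmark phenotype (`penetrance`); hallmark
cells are a subset of exporting cells.

**Gradual.** The observable the ~9 h figure refers to is the C:N ratio's
min-to-max window, so the generator schedules export in *measured space*:
a per-cell window `T ~ N(9.0, 3.4) h` (resampled positive) starting
shortly after the cell's Rev onset, over which the target C:N ramps
linearly from 0 to `c_end`. The target is inverted to a labeled-export
count via `n(t) = c(t)·Y_tot / (48·(c(t) + s))`, and the engine exports
*exactly* the scheduled number of labeled transcripts (sampled without
replacement each 30 s bookkeeping step). Two numerical details matter:
the target count is rounded (so realized exports neither lead nor lag the
schedule on average) and selection is exact rather than per-particle
Bernoulli (independent draws can only overshoot, never undo, and near the
saturating top of the C:N curve a single extra transcript advances the
apparent ramp by the better part of an hour). An earlier design that
ramped the exported *fraction* linearly was discarded: the C:N ratio is
convex in the exported fraction, which biased the downstream 10–90%
duration estimator low by ~40%.

**Burst.** Export is suppressed until the nuclear transcript count
reaches `burst_threshold` (50, the same scale as pool saturation) and
Rev is expressed; the cell then evacuates all nuclear transcripts over
`burst_duration_h` (0.5 h — "well under an hour", chosen so the 30-min
camera cadence still measures the transition below the 1 h burst
criterion). Dark transcripts born later leave at the basal rate, keeping
the post-burst nuclear count below 10% of its peak.

**CTE / MTOC.** Export is a constant per-transcript rate
(`k_exp_max` = 0.5/h). In hallmark cells, exported transcripts within a
1 μm envelope-contact band (or near the MTOC) attach to microtubules with
probability 0.25 per 10 s step, then run along straight rays through the
centrosome at 0.6 μm/s with exponential run lengths (mean 2 μm) and a
net minus-end bias (each run ends toward the centrosome with probability
0.7). Reaching the capture radius (1 μm) parks the transcript at the
MTOC for an exponential dwell (mean 240 s) before releasing it to the
adjacent cytoplasm, where it typically re-attaches — a dynamic cluster
with bidirectional excursions. Non-hallmark exporters disperse by
diffusion.

**Nocodazole.** Without microtubules the export machinery arrests at the
nuclear membrane, so transcripts neither attach nor leave: they stay
docked in a 2 μm rim inside the envelope (the bright nuclear-rim images
drug-treated cells show), and MTOC occupancy is identically zero.

Diffusion uses D_nuc = 0.05 and D_cyt = 0.5 μm²/s with reflecting
boundaries (nuclear envelope, cell outline); positions are checked
against the nucleus again after the boundary clamp because the clamp
pulls particles toward the cell centre and an off-centre nucleus can
swallow them otherwise. Dynamics are integrated at a 10 s internal step
in the long mode; the fast mode shrinks the step to half the 700 ms frame
interval, since a 10 s step cannot resolve sub-second frames. Export
bookkeeping runs every third step (30 s). Degradation is off by default
(turnover is never quantified in the source data).

Fast-mode runs can seed each cell with transcripts already exported
(`n_initial_cyt`), modeling joining a cell mid-way through its export
program without integrating hours of prior dynamics at sub-second
resolution.

## Reporters

Rev-mCherry is zero until a per-cell onset ~ N(7, 2) h and rises linearly
to saturation over 6 h, rendered 60% nuclear / 40% cytoplasmic (the
partition is not quantified in the source data; the split is a documented
convention). Gag-CFP accumulates at `k_translate` = 2 units per
cytoplasmic transcript per hour, spread over the cytoplasm, with a 10%
MTOC-accumulation term in CTE scenarios. Membrane VLP punctae appear only
in exporting cells at a per-cell onset drawn from a left-truncated normal
whose parameters are *solved numerically* so the realized (truncated)
mean and SD equal the published moments (16.7 ± 8.06 h CTE,
20.3 ± 8.07 h Rev, none before 5 h) — naive truncation of
N(16.7, 8.06) at 5 h would inflate the realized mean by ~7%. Three
punctae appear at onset (so the ≥3-sustained detection rule fires within
one frame) and grow to at most 12.

## Optics and rendering

Diffuse pools are spread uniformly over their compartment and blurred
with a Gaussian PSF (σ = 0.4 μm); transcripts are stamped as unit-flux
Gaussian spots of the same width at subpixel positions. The camera
applies Poisson noise to `signal · photon_scale + background` (default
background 100 counts) plus Gaussian read noise (SD 2), then rounds to
uint16; >1% saturated pixels logs a warning. `noiseless=True` gives the
infinite-photon limit used by calibration oracles. A 15 counts/px
cell-body autofluorescence underlies all channels — it is what makes the
cell outline segmentable in conditions with no cytoplasmic reporter.

Nuclear transcript spots in nuclear-retention scenarios are calibrated in
measured space: each frame, the spot amplitude is set so the spot-disk /
nucleoplasm ratio equals the scenario's configured enrichment fold
(2.8 by default). The calibration constant — the mean disk value of a
unit-flux spot — is evaluated on the actual pixel lattice averaged over
subpixel offsets; the analytic continuous-disk formula is ~15% off at
these spot sizes. Exporting scenarios instead give every labeled
transcript a fixed flux proportional to its 48 bound coats, so the
rendered C:N ratio follows the simulator's content bookkeeping.

## Measurement conventions

* Nucleus: Otsu on the σ=2 px smoothed DNA channel, refined to the
  half-maximum contour (Otsu under-thresholds when background dominates
  the histogram), rim pixels re-tested against the raw image (smoothing
  walks convex contours outward by ~0.15 px), holes filled, largest
  component, ≥200 px.
* Cell: triangle threshold on the smoothed non-DNA channel sum, floored
  at `border median + 4·MAD` (in dim-cytoplasm cells the triangle split
  can land between cytoplasm and the bright nucleus), closed, eroded by
  the smoothing radius, the component containing the nucleus.
* Background: median over a 10 px annulus outside the cell; fewer than
  50 surviving pixels warns and uses what is available.
* Compartment MFI: background-subtracted means clamped at zero. The
  nuclear mean uses the nucleus eroded by 5 px: single transcripts are
  ~300× brighter per pixel than the residual pool, and their PSF tails
  bleeding across the envelope would otherwise both bias the nuclear MFI
  and make it swing frame-to-frame as spots wander past the mask edge.
  The cytoplasmic mean uses the full compartment so every transcript's
  flux counts wherever it diffuses.
* Punctae: scale-normalized LoG at the PSF scale, threshold 5×MAD of the
  in-mask response, intensity-weighted subpixel centroids, detections
  closer than 2σ merged. Enrichment divides each spot disk (r = 2σ) by
  the nucleoplasm with all spot zones excised *and* restricted to the
  eroded nuclear interior (the rim rolloff would dilute the reference and
  inflate every fold by ~10%).
* Kinetics: onsets require 2 consecutive frames above threshold;
  transition duration is `(t_last_cross 0.9 − t_first_cross 0.1)/0.8`
  with linear interpolation — exact for linear ramps; burst = duration
  < 1 h with final C:N ≥ 1.5.
* Phenotype: C:N ≥ 1.5 cytoplasmic, ≤ 1/1.5 nuclear, equal between;
  MTOC targeting = ≥3-fold disk (3 μm) over remaining cytoplasm with a
  small absolute disk-MFI floor (5 counts) so empty cells cannot score on
  0/0 noise. Population pipelines additionally exclude a 5 px perinuclear
  band from the scoring cytoplasm: under nocodazole the envelope-docked
  transcripts' PSF bleed into the juxtanuclear disk would otherwise mimic
  a cluster.
* Tracking: greedy mutual-nearest-neighbour linking (deterministic,
  distance-then-index tie-breaks, 1-frame gap closing, 1.5 μm/frame
  search radius), oracle-checked against optimal assignment; speed is the
  mean per-step displacement above a noise floor (2× localization error);
  the MSD exponent is fitted over the first quarter of lags with
  0.7 / 1.3 class boundaries. Directed-class tracks define the
  transport-speed estimate, mirroring the original analysis of
  MT-associated runs.

The membrane band used for VLP counting is the outer ~2.6 μm (8 px) of
the segmented cell: wide enough to tolerate the few-pixel mismatch
between the segmented outline and the true membrane, while still
excluding interior structures like the MTOC.

## Problem sizes

Population pipelines default to desk scale: 160×160 px fields, 30-min
frames, 300 cells in 3 replicates for penetrance readouts, 100 cells for
burst classification, 30 for transition durations, 50 per pathway for VLP
onsets, 200 for the M-PMV cohort, and 8 fast-mode cells of ~150 frames
(≥50 directed tracks) for speed recovery. Cohorts are simulated in a
single vectorized pass over all particles of all cells. Cohort pipelines
segment each movie once, at the endpoint, and reuse the masks across
frames — simulated cells do not move.

## What passing recovery shows — and what it does not

The synthetic movies share the key statistical obstacles of the real
ones: shot noise on a dim residual nuclear signal, PSF mixing across the
nuclear envelope, discrete bright particles against diffuse pools,
segmentation imperfection, and camera-cadence aliasing of sub-hour
events. They omit cell migration and shape change, focus drift,
photobleaching, 3-D sectioning, multi-cell crowding, mitosis, and any
mismatch between the assumed and the true generative kinetics (real
bursts are not scheduled evacuations). Recovery therefore validates the
*measurement pipeline* under realistic noise, and the simulator as a
self-consistent model of the published phenotypes — not the biological
correctness of the generative assumptions themselves.

## Known limitations

* The greedy linker degrades at spot densities far above the simulated
  ~30 spots per field; it is not a multiple-hypothesis tracker.
* MT rays are straight and may traverse the nucleus footprint in 2-D
  projection; real microtubules bend around it.
* The C:N schedule's measured-space inversion uses the true geometric
  area ratio; segmentation error makes the realized endpoint C:N differ
  from the target by a few percent (scale-free readouts are unaffected).
* The transition-duration estimator's last-crossing rule is sensitive to
  plateau noise when the plateau is long and the relative noise exceeds
  a few percent; the pool-residual design keeps it near 1%.
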