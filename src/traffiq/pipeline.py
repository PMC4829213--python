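"""End-to-end experiment orchestration: simulate -> render -> measure -> call.

Each ``run_*`` helper reproduces one published readout as a parameter
recovery through the full chain — the simulator generates ground truth
from registry parameters, the renderer turns it into noisy images, and
only the measurement operators see those images.  ``run_experiment``
bundles the readouts for one scenario into a deterministic JSON-able
report.

Problem sizes default to desk scale (hundreds of cells, 160-px fields at
30-min cadence for the long mode); every helper accepts explicit sizes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import __version__
from .kinetics import (
    CellTrace, classify_export, cn_ratio, normalize_minmax,
    transition_duration, vlp_onset,
)
from .measure import (
    CompartmentMasks, compartment_mfi, detect_punctae, estimate_background,
    make_masks, punctae_enrichment,
)
from .phenotype import (
    PhenotypeCall, classify_distribution, locate_centrosome,
    mtoc_enrichment, population_summary,
)
from .render import Movie, OpticsConfig, render_movie
from .scenarios import (
    ConfigurationError, ScenarioConfig, scenario_registry, simulate_cohort,
)
from .tracking import classify_motion, link_tracks, track_speed

__all__ = [
    "RunConfig", "long_mode_optics", "fast_mode_optics",
    "simulate_and_render_endpoint", "measure_traces",
    "run_punctae_enrichment", "run_phenotype_fractions",
    "run_transition_durations", "run_export_classes", "run_vlp_onsets",
    "run_mtoc_fractions", "run_tracking", "run_experiment",
]

LONG_SHAPE = (160, 160)
FAST_SHAPE = (448, 448)


@dataclass
class RunConfig:
    """One orchestrated experiment: scenario, cohort size, mode, seed."""

    scenario: str = "RRE_Rev"
    n_cells: int = 30
    n_replicates: int = 1
    seed: int = 0
    mode: str = "long"
    t_end_h: float = 24.0
    optics_overrides: dict = field(default_factory=dict)
    out_dir: str | None = None

    def validate(self) -> "RunConfig":
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.mode not in ("long", "fast"):
            raise ConfigurationError("mode must be 'long' or 'fast'")
        if self.scenario not in scenario_registry():
            raise ConfigurationError(f"unknown scenario: {self.scenario!r}")
        return self


def long_mode_optics(channels=("YFP", "CFP", "mCherry", "DNA"), **overrides) -> OpticsConfig:
    """30-min-cadence, 20x-like acquisition over a 52-um field."""
    kw = dict(
        pixel_size_um=0.325, frame_interval=30.0, mode="long",
        channels=tuple(channels), image_shape=LONG_SHAPE,
    )
    kw.update(overrides)
    return OpticsConfig(**kw).validate()


def fast_mode_optics(channels=("YFP",), **overrides) -> OpticsConfig:
    """700-ms-cadence, 100x-like acquisition for single-particle tracking."""
    kw = dict(
        pixel_size_um=0.065, frame_interval=0.7, mode="fast",
        channels=tuple(channels), image_shape=FAST_SHAPE,
    )
    kw.update(overrides)
    return OpticsConfig(**kw).validate()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s) % (2**31 - 1) for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# Shared building blocks
# ---------------------------------------------------------------------------

def simulate_and_render_endpoint(
    config: ScenarioConfig, n_cells: int, seed: int,
    t_end_h: float = 24.0, channels=("YFP", "CFP", "mCherry", "DNA"),
):
    """Cohort ground truth plus a rendered endpoint frame per cell."""
    sim_seed, render_seed = _spawn_seeds(seed, 2)
    histories = simulate_cohort(
        config, n_cells, sim_seed, t_end_h=t_end_h, frame_interval_h=t_end_h,
    )
    optics = long_mode_optics(channels=channels)
    movies = [
        render_movie(h, h.geometry, optics, render_seed + 13 * i,
                     frame_indices=np.array([len(h.times_h) - 1]))
        for i, h in enumerate(histories)
    ]
    return histories, movies


def measure_traces(
    config: ScenarioConfig, n_cells: int, seed: int,
    t_end_h: float = 24.0, frame_interval_min: float = 30.0,
    trace_channel: str = "YFP",
) -> tuple[list, list[CellTrace]]:
    """Full-chain per-cell traces of one channel at the long-mode cadence.

    Masks come from a full-channel endpoint render of the same cell
    (simulated cells are stationary, so segmentation is done once); the
    trace channel is rendered and measured at every frame.
    """
    sim_seed, render_seed = _spawn_seeds(seed, 2)
    histories = simulate_cohort(
        config, n_cells, sim_seed,
        t_end_h=t_end_h, frame_interval_h=frame_interval_min / 60.0,
    )
    endpoint_optics = long_mode_optics()
    trace_optics = long_mode_optics(channels=(trace_channel,))
    traces = []
    for i, h in enumerate(histories):
        end_movie = render_movie(
            h, h.geometry, endpoint_optics, render_seed + 13 * i,
            frame_indices=np.array([len(h.times_h) - 1]),
        )
        masks = make_masks(end_movie)
        movie = render_movie(h, h.geometry, trace_optics, render_seed + 13 * i + 7)
        ci = movie.channel_index(trace_channel)
        T = movie.data.shape[0]
        nuc = np.empty(T)
        cyt = np.empty(T)
        for fi in range(T):
            frame = movie.data[fi, ci]
            bg = estimate_background(frame, masks)
            nuc[fi], cyt[fi] = compartment_mfi(frame, masks, bg)
        traces.append(
            CellTrace(time_h=movie.times_h.copy(), nuclear_mfi=nuc, cytoplasmic_mfi=cyt)
        )
    return histories, traces


def _boundary_band(cell_mask: np.ndarray, width_px: int = 8) -> np.ndarray:
    """Membrane band: pixels within ``width_px`` of the segmented cell edge.

    Wide enough (~2.6 um) to tolerate the few-pixel mismatch between the
    segmented outline and the true plasma membrane while still excluding
    interior structures such as the MTOC.
    """
    eroded = ndimage.binary_erosion(cell_mask, iterations=width_px)
    return cell_mask & ~eroded


# ---------------------------------------------------------------------------
# Readout recoveries
# ---------------------------------------------------------------------------

def run_punctae_enrichment(
    seed: int, n_cells: int = 20, scenario: str = "RRE_noRev",
    t_h: float = 4.0, min_spots: int = 100,
) -> dict:
    """Mean fold enrichment of nuclear punctae over the nucleoplasm.

    Simulates nuclear-retention cells, renders at default optics/noise,
    detects punctae and measures enrichment across all cells' spots.
    """
    config = scenario_registry()[scenario]
    histories, movies = simulate_and_render_endpoint(
        config, n_cells, seed, t_end_h=t_h,
    )
    folds = []
    n_spots = 0
    for movie in movies:
        masks = make_masks(movie)
        frame = movie.data[0, movie.channel_index("YFP")]
        bg = estimate_background(frame, masks)
        spots = detect_punctae(
            frame, masks.nucleus, channel="YFP",
            psf_sigma_px=movie.optics.psf_sigma_px, background=bg,
        )
        if not spots:
            continue
        n_spots += len(spots)
        mean_fold, _ = punctae_enrichment(
            spots, frame, masks.nucleus, bg, movie.optics.psf_sigma_px
        )
        folds.extend([mean_fold] * len(spots))   # spot-weighted grand mean
    if n_spots < min_spots:
        raise RuntimeError(
            f"only {n_spots} punctae detected; increase n_cells for >= {min_spots}"
        )
    return {
        "mean_fold": float(np.mean(folds)),
        "sd_fold": float(np.std(folds, ddof=1)),
        "n_spots": int(n_spots),
        "configured_fold": config.punctae_enrichment_fold,
    }


def run_phenotype_fractions(
    seed: int, scenario: str = "RRE_Rev", n_cells: int = 300,
    n_replicates: int = 3, t_end_h: float = 36.0,
) -> dict:
    """Endpoint nuclear/cytoplasmic/equal fractions with replicate SD."""
    config = scenario_registry()[scenario]
    per_rep = n_cells // n_replicates
    seeds = _spawn_seeds(seed, n_replicates + 2)
    calls = []
    for rep in range(n_replicates):
        _, movies = simulate_and_render_endpoint(
            config, per_rep, seeds[rep], t_end_h=t_end_h,
        )
        for i, movie in enumerate(movies):
            masks = make_masks(movie)
            frame = movie.data[0, movie.channel_index("YFP")]
            bg = estimate_background(frame, masks)
            nuc, cyt = compartment_mfi(frame, masks, bg)
            calls.append(
                PhenotypeCall(
                    cell_id=rep * per_rep + i,
                    distribution_class=classify_distribution(nuc, cyt),
                    replicate_id=rep,
                )
            )
    summary = population_summary(calls)
    summary["n_cells"] = len(calls)
    summary["configured_fraction"] = config.frac_exporting
    return summary


def run_transition_durations(
    seed: int, scenario: str = "RRE_Rev", n_cells: int = 30,
    t_end_h: float = 30.0,
) -> dict:
    """Mean measured C:N min-to-max duration for gradual-mode cells."""
    config = scenario_registry()[scenario].replace(
        export_mode="gradual", penetrance=1.0, frac_exporting=1.0,
    )
    histories, traces = measure_traces(config, n_cells, seed, t_end_h=t_end_h)
    durations = []
    drawn = []
    for h, tr in zip(histories, traces):
        cn = cn_ratio(tr.nuclear_mfi, tr.cytoplasmic_mfi)
        finite = np.isfinite(cn)
        if finite.sum() < 3:
            continue
        norm = normalize_minmax(np.where(finite, cn, np.nan))
        d = transition_duration(norm, tr.time_h)
        if np.isfinite(d):
            durations.append(d)
            drawn.append(h.program.transition_h)
    return {
        "mean_duration_h": float(np.mean(durations)),
        "sd_duration_h": float(np.std(durations, ddof=1)),
        "n_cells": len(durations),
        "mean_drawn_h": float(np.mean(drawn)),
        "configured_mean_h": config.transition_duration_mean_h,
    }


def run_export_classes(
    seed: int, scenario: str = "RRE_Rev", n_cells: int = 100,
    n_replicates: int = 1, t_end_h: float = 24.0,
) -> dict:
    """Burst / gradual / none fractions from measured C:N traces."""
    config = scenario_registry()[scenario]
    per_rep = n_cells // n_replicates
    seeds = _spawn_seeds(seed, n_replicates + 2)
    rep_fracs = {"burst": [], "gradual": [], "none": []}
    n_total = 0
    for rep in range(n_replicates):
        _, traces = measure_traces(config, per_rep, seeds[rep], t_end_h=t_end_h)
        n_total += len(traces)
        counts = {"burst": 0, "gradual": 0, "none": 0}
        for tr in traces:
            cn = cn_ratio(tr.nuclear_mfi, tr.cytoplasmic_mfi)
            cls, dur = classify_export(cn, tr.time_h)
            tr.export_class, tr.transition_duration_h = cls, dur
            counts[cls] += 1
        for k in rep_fracs:
            rep_fracs[k].append(counts[k] / per_rep)
    out = {}
    for k, vals in rep_fracs.items():
        arr = np.asarray(vals)
        out[k] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        }
    out["n_cells"] = n_total
    out["configured_burst"] = config.penetrance if config.export_mode == "burst" else 0.0
    return out


def run_vlp_onsets(
    seed: int, scenario: str = "4xCTE", n_cells: int = 50,
    t_end_h: float = 40.0,
) -> dict:
    """Mean VLP assembly onset from membrane punctae in the Gag channel."""
    config = scenario_registry()[scenario]
    sim_seed, render_seed = _spawn_seeds(seed, 2)
    histories = simulate_cohort(
        config, n_cells, sim_seed, t_end_h=t_end_h, frame_interval_h=0.5,
    )
    endpoint_optics = long_mode_optics()
    cfp_optics = long_mode_optics(channels=("CFP",))
    onsets = []
    drawn = []
    for i, h in enumerate(histories):
        end_movie = render_movie(
            h, h.geometry, endpoint_optics, render_seed + 13 * i,
            frame_indices=np.array([len(h.times_h) - 1]),
        )
        masks = make_masks(end_movie)
        band = _boundary_band(masks.cell)
        movie = render_movie(h, h.geometry, cfp_optics, render_seed + 13 * i + 7)
        ci = movie.channel_index("CFP")
        counts = np.empty(movie.data.shape[0])
        for fi in range(movie.data.shape[0]):
            spots = detect_punctae(
                movie.data[fi, ci], band, channel="CFP",
                psf_sigma_px=movie.optics.psf_sigma_px, frame_index=fi,
            )
            counts[fi] = len(spots)
        onset = vlp_onset(counts, movie.times_h)
        if np.isfinite(onset):
            onsets.append(onset)
        if h.program.exports:
            drawn.append(h.program.vlp_onset_h)
    return {
        "mean_onset_h": float(np.mean(onsets)) if onsets else float("nan"),
        "sd_onset_h": float(np.std(onsets, ddof=1)) if len(onsets) > 1 else float("nan"),
        "earliest_onset_h": float(np.min(onsets)) if onsets else float("nan"),
        "n_cells_with_onset": len(onsets),
        "mean_drawn_h": float(np.mean(drawn)) if drawn else float("nan"),
        "configured_mean_h": config.vlp_onset_mean_h,
    }


def run_mtoc_fractions(
    seed: int, scenario: str = "4xCTE", n_cells: int = 100,
    n_replicates: int = 1, t_end_h: float = 24.0,
) -> dict:
    """Fraction of cells with MS2-YFP signal clustered at the centrosome."""
    config = scenario_registry()[scenario]
    per_rep = n_cells // n_replicates
    seeds = _spawn_seeds(seed, n_replicates + 2)
    rep_fracs = []
    folds_all = []
    n_total = 0
    for rep in range(n_replicates):
        _, movies = simulate_and_render_endpoint(
            config, per_rep, seeds[rep], t_end_h=t_end_h,
            channels=("YFP", "CFP", "mCherry", "DNA", "PCNT"),
        )
        targeted = 0
        for movie in movies:
            masks = make_masks(movie)
            yfp = movie.data[0, movie.channel_index("YFP")]
            pcnt = movie.data[0, movie.channel_index("PCNT")]
            bg = estimate_background(yfp, masks)
            # exclude a perinuclear band so PSF bleed from envelope-docked
            # transcripts (e.g. under nocodazole) cannot mimic a cluster
            scoring_cyt = masks.cytoplasm & ~ndimage.binary_dilation(
                masks.nucleus, iterations=5
            )
            loc = locate_centrosome(
                pcnt, scoring_cyt, movie.optics.psf_sigma_px
            )
            if loc is None:
                continue
            fold, is_t = mtoc_enrichment(
                yfp, loc, scoring_cyt, bg,
                pixel_size_um=movie.optics.pixel_size_um,
            )
            folds_all.append(fold)
            targeted += int(is_t)
        rep_fracs.append(targeted / per_rep)
        n_total += per_rep
    arr = np.asarray(rep_fracs)
    return {
        "targeted_fraction": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        "n_cells": n_total,
        "configured_penetrance": config.penetrance,
        "median_fold": float(np.nanmedian(folds_all)) if folds_all else float("nan"),
    }


def run_tracking(
    seed: int, scenario: str = "4xCTE", n_cells: int = 8,
    n_frames: int = 160, n_initial: int = 25, min_tracks: int = 50,
) -> dict:
    """Fast-mode detection, linking and speed recovery of MT transport.

    Only tracks classified directed contribute to the speed estimate —
    freely diffusing and nucleoplasmic transcripts are excluded the same
    way the published rates considered MT-associated runs.
    """
    config = scenario_registry()[scenario].replace(
        cell_radius_um=10.0, cell_radius_sd_um=0.8, penetrance=1.0,
        frac_exporting=1.0,
    )
    sim_seed, render_seed = _spawn_seeds(seed, 2)
    optics = fast_mode_optics()
    dt_h = optics.frame_interval_h
    t_end_h = n_frames * dt_h
    histories = simulate_cohort(
        config, n_cells, sim_seed, t_end_h=t_end_h,
        frame_interval_h=dt_h, n_initial_cyt=n_initial,
    )
    all_tracks = []
    for i, h in enumerate(histories):
        movie = render_movie(h, h.geometry, optics, render_seed + 13 * i)
        ci = movie.channel_index("YFP")
        full = np.ones(optics.image_shape, dtype=bool)
        per_frame = []
        for fi in range(movie.data.shape[0]):
            spots = detect_punctae(
                movie.data[fi, ci], full, channel="YFP",
                psf_sigma_px=movie.optics.psf_sigma_px, frame_index=fi,
            )
            xy_um = np.array(
                [[s.x_px * optics.pixel_size_um, s.y_px * optics.pixel_size_um]
                 for s in spots]
            ).reshape(-1, 2)
            per_frame.append(xy_um)
        tracks = link_tracks(per_frame, movie.times_h * 3600.0)
        all_tracks.extend(tracks)
    speeds = []
    n_directed = 0
    n_classified = 0
    for tr in all_tracks:
        if len(tr) < 10:
            continue
        classify_motion(tr)
        n_classified += 1
        if tr.motion_class == "directed":
            track_speed(tr)
            if not tr.stationary:
                speeds.append(tr.mean_speed)
                n_directed += 1
    if n_directed < min_tracks:
        raise RuntimeError(
            f"only {n_directed} directed tracks; increase n_cells/n_initial"
        )
    return {
        "mean_speed_um_s": float(np.mean(speeds)),
        "sd_speed_um_s": float(np.std(speeds, ddof=1)),
        "n_directed_tracks": n_directed,
        "n_classified_tracks": n_classified,
        "configured_speed_um_s": config.mt_speed_um_s,
    }


# ---------------------------------------------------------------------------
# Orchestrated report
# ---------------------------------------------------------------------------

def run_experiment(run_config: RunConfig) -> dict:
    """Execute the full pipeline for one scenario and assemble a report.

    Long mode: endpoint phenotype fractions, export-class fractions,
    transition durations (when the scenario exports) and MTOC scoring
    (when the scenario is microtubule-directed).  Fast mode: tracking.
    Identical seed and config give an identical report.
    """
    rc = run_config.validate()
    config = scenario_registry()[rc.scenario]
    seeds = _spawn_seeds(rc.seed, 8)
    report: dict = {
        "package_version": __version__,
        "scenario": rc.scenario,
        "seed": rc.seed,
        "n_cells": rc.n_cells,
        "mode": rc.mode,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=list).encode()
        ).hexdigest()[:16],
    }
    if rc.mode == "fast":
        report["tracking"] = run_tracking(
            seeds[0], scenario=rc.scenario,
            n_cells=max(rc.n_cells, 4), min_tracks=10,
        )
        return report

    report["phenotype"] = run_phenotype_fractions(
        seeds[1], scenario=rc.scenario, n_cells=rc.n_cells,
        n_replicates=rc.n_replicates, t_end_h=rc.t_end_h,
    )
    report["export_classes"] = run_export_classes(
        seeds[2], scenario=rc.scenario, n_cells=rc.n_cells,
        n_replicates=rc.n_replicates, t_end_h=rc.t_end_h,
    )
    if config.export_mode in ("gradual", "burst"):
        report["transition"] = run_transition_durations(
            seeds[3], scenario=rc.scenario, n_cells=min(rc.n_cells, 30),
        )
        report["vlp"] = run_vlp_onsets(
            seeds[4], scenario=rc.scenario, n_cells=min(rc.n_cells, 50),
        )
    if config.export_mode == "none":
        report["punctae"] = run_punctae_enrichment(
            seeds[5], scenario=rc.scenario, n_cells=min(rc.n_cells, 20),
        )
    if config.export_mode == "cte_mtoc":
        report["mtoc"] = run_mtoc_fractions(
            seeds[6], scenario=rc.scenario, n_cells=rc.n_cells,
            n_replicates=rc.n_replicates, t_end_h=rc.t_end_h,
        )
        report["vlp"] = run_vlp_onsets(
            seeds[4], scenario=rc.scenario, n_cells=min(rc.n_cells, 50),
        )
    return report
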