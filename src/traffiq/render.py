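"""Synthetic fluorescence-microscopy rendering of simulated cells.

Ground-truth particle histories are converted to multichannel uint16
time-lapse stacks with a calibrated optical model:

* every fluorophore population contributes an *expected photon image* —
  diffuse pools are spread uniformly over their compartment and blurred by
  an isotropic 2-D Gaussian point-spread function, single transcripts are
  stamped as Gaussian spots of the same width;
* the camera applies Poisson shot noise to ``signal * photon_scale +
  background`` and additive Gaussian read noise, then quantizes to 16 bits.

Channel semantics follow the three-color reporter system: YFP carries the
MS2-labeled gRNA signal (free nuclear coat-protein pool plus transcript
spots), CFP the Gag reporter (cytoplasmic pool plus membrane VLP punctae,
and an MTOC accumulation term in the CTE scenarios), mCherry the Rev level
split 60/40 between nucleus and cytoplasm, DNA a uniform nucleus fill, and
the optional PCNT channel a single bright centrosome marker spot.

Nuclear transcript spots in the nuclear-retention scenarios are calibrated
in *measured* space: the spot amplitude is chosen each frame so that the
spot-disk / nucleoplasm intensity ratio equals the scenario's configured
punctae-enrichment fold.  Exporting scenarios instead give each labeled
transcript a fixed flux proportional to its bound coat count, so the
rendered C:N ratio tracks the simulator's content bookkeeping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .scenarios import (
    CYTOPLASMIC, MT_BOUND, MTOC, NUCLEAR,
    CellGeometry, ConfigurationError, ParticleHistory, N_THETA,
)

logger = logging.getLogger("traffiq.render")

__all__ = [
    "OpticsConfig", "Movie", "FormatError",
    "render_movie", "write_movie", "read_movie",
    "stamp_gaussian_spots", "geometry_masks", "spot_disk_mass_fraction",
]


class FormatError(ValueError):
    """Raised when an on-disk movie is malformed or incomplete."""


DEFAULT_CHANNELS = ("YFP", "CFP", "mCherry", "DNA")


@dataclass
class OpticsConfig:
    """Acquisition and camera model.

    ``frame_interval`` is in minutes for the long acquisition mode (images
    every 30–60 min over many hours) and in seconds for the fast mode
    (sub-second single-particle tracking); ``frame_interval_h`` resolves
    the unit.  ``photon_scale`` converts fluorescence units to expected
    photons; ``noiseless=True`` is the infinite-photon limit used by
    calibration oracles (no shot or read noise).
    """

    pixel_size_um: float = 0.325
    psf_sigma_um: float = 0.4
    photon_scale: float = 1.0
    read_noise_sd: float = 2.0
    background_level: float = 100.0
    bit_depth: int = 16
    frame_interval: float = 30.0
    mode: str = "long"                  # {"long", "fast"}
    channels: tuple = DEFAULT_CHANNELS
    image_shape: tuple = (256, 256)
    noiseless: bool = False

    # flux calibration (counts per fluorescence unit / per object)
    yfp_flux_per_unit: float = 400.0
    gag_flux_per_unit: float = 18.0
    rev_flux: float = 160000.0          # whole-cell mCherry flux at rev_level=1
    dna_density: float = 250.0          # counts/px over the nucleus
    vlp_flux: float = 9000.0            # per membrane punctum
    pcnt_flux: float = 20000.0          # centrosome marker spot
    autofluor_density: float = 15.0     # counts/px over the whole cell body
    mtoc_gag_fraction: float = 0.10     # CFP accumulation term (CTE mode)

    def validate(self) -> "OpticsConfig":
        for f in ("pixel_size_um", "psf_sigma_um", "frame_interval"):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"{f} must be positive")
        if self.mode not in ("long", "fast"):
            raise ConfigurationError(f"mode must be 'long' or 'fast', got {self.mode!r}")
        if self.bit_depth != 16:
            raise ConfigurationError("only 16-bit rendering is supported")
        return self

    @property
    def frame_interval_h(self) -> float:
        return self.frame_interval / 60.0 if self.mode == "long" else self.frame_interval / 3600.0

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsConfig":
        d = dict(d)
        for key in ("channels", "image_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()


@dataclass
class Movie:
    """Rendered multichannel uint16 stack with calibration metadata."""

    data: np.ndarray                    # (T, C, H, W) uint16
    optics: OpticsConfig
    scenario: str
    seed: int
    times_h: np.ndarray                 # (T,)
    nucleus_mask: np.ndarray            # (H, W) bool
    cell_mask: np.ndarray               # (H, W) bool
    centrosome_px: np.ndarray           # (2,) -> (x, y)
    spots: pd.DataFrame                 # frame, channel, x_px, y_px, flux

    def validate(self) -> "Movie":
        T, C, H, W = self.data.shape
        if C != len(self.optics.channels):
            raise FormatError(
                f"channel count {C} does not match metadata "
                f"({len(self.optics.channels)} channels)"
            )
        if self.nucleus_mask.shape != (H, W) or self.cell_mask.shape != (H, W):
            raise FormatError("ground-truth masks do not match image bounds")
        if self.data.dtype != np.uint16:
            raise FormatError("movie data must be uint16")
        if len(self.times_h) != T:
            raise FormatError("times_h length does not match frame count")
        return self

    def channel_index(self, name: str) -> int:
        try:
            return self.optics.channels.index(name) if isinstance(
                self.optics.channels, list
            ) else list(self.optics.channels).index(name)
        except ValueError:
            raise FormatError(f"channel {name!r} not present in movie") from None


# ---------------------------------------------------------------------------
# Low-level painters
# ---------------------------------------------------------------------------

def spot_disk_mass_fraction() -> float:
    """Fraction of a 2-D Gaussian's mass inside a disk of radius 2 sigma."""
    return 1.0 - math.exp(-2.0)


def measured_disk_mean(sigma_px: float) -> float:
    """Mean pixel value inside the r = 2 sigma measurement disk for a
    unit-flux Gaussian spot, on the actual pixel grid.

    This is the brute-force calibration constant linking a spot's rendered
    flux to the disk MFI the enrichment operator measures; evaluating it on
    the pixel lattice (averaged over subpixel offsets) rather than in the
    continuum removes the pixelation bias of the analytic mass fraction.
    """
    r = 2.0 * sigma_px
    R = int(math.ceil(r)) + 2
    vals = []
    for ox, oy in ((0.0, 0.0), (0.5, 0.0), (0.0, 0.5), (0.5, 0.5)):
        yy, xx = np.mgrid[-R:R + 1, -R:R + 1].astype(float)
        g = np.exp(-0.5 * (((xx - ox) ** 2 + (yy - oy) ** 2) / sigma_px ** 2))
        g /= 2 * math.pi * sigma_px ** 2
        disk = (xx - ox) ** 2 + (yy - oy) ** 2 <= r ** 2
        vals.append(g[disk].sum() / disk.sum())
    return float(np.mean(vals))


def stamp_gaussian_spots(
    img: np.ndarray, xy_px: np.ndarray, flux: np.ndarray, sigma_px: float
) -> None:
    """Add Gaussian spots (total integrated ``flux`` each) to ``img`` in place.

    Subpixel positions are honored by evaluating the Gaussian on the pixel
    grid around each spot; all spots are stamped in one vectorized batch.
    """
    if len(xy_px) == 0:
        return
    H, W = img.shape
    R = int(math.ceil(4.0 * sigma_px))
    k = 2 * R + 1
    x0 = np.floor(xy_px[:, 0]).astype(int)
    y0 = np.floor(xy_px[:, 1]).astype(int)
    off = np.arange(-R, R + 1)
    gx = x0[:, None] + off[None, :]                       # (S, k)
    gy = y0[:, None] + off[None, :]
    dx = gx - xy_px[:, 0][:, None]
    dy = gy - xy_px[:, 1][:, None]
    norm = flux / (2 * math.pi * sigma_px ** 2)
    ex = np.exp(-0.5 * (dx / sigma_px) ** 2)              # (S, k)
    ey = np.exp(-0.5 * (dy / sigma_px) ** 2)
    patch = norm[:, None, None] * ey[:, :, None] * ex[:, None, :]   # (S, k, k)
    yy = np.broadcast_to(gy[:, :, None], (len(xy_px), k, k))
    xx = np.broadcast_to(gx[:, None, :], (len(xy_px), k, k))
    ok = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
    np.add.at(img, (yy[ok], xx[ok]), patch[ok])


def geometry_masks(geometry: CellGeometry, optics: OpticsConfig):
    """Rasterize the ground-truth nucleus and cell masks (pixel space)."""
    H, W = optics.image_shape
    ps = optics.pixel_size_um
    cx, cy = W / 2.0, H / 2.0
    xs = (np.arange(W) - cx) * ps
    ys = (np.arange(H) - cy) * ps
    X, Y = np.meshgrid(xs, ys)
    th = np.mod(np.arctan2(Y, X), 2 * np.pi)
    bins = np.round(th / (2 * np.pi) * N_THETA).astype(int) % N_THETA
    rb = geometry.boundary_radii[bins]
    cell = np.hypot(X, Y) <= rb
    a, b = geometry.nucleus_semiaxes
    ncx, ncy = geometry.nucleus_center
    nucleus = np.hypot((X - ncx) / a, (Y - ncy) / b) <= 1.0
    return nucleus & cell, cell


def um_to_px(xy_um: np.ndarray, optics: OpticsConfig) -> np.ndarray:
    """Cell-centred micrometre coordinates to 0-based pixel (x=column)."""
    H, W = optics.image_shape
    out = np.empty_like(np.atleast_2d(xy_um), dtype=float)
    out[:, 0] = xy_um[..., 0] / optics.pixel_size_um + W / 2.0
    out[:, 1] = xy_um[..., 1] / optics.pixel_size_um + H / 2.0
    return out


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def _blurred_fill(mask: np.ndarray, sigma_px: float) -> np.ndarray:
    """Unit-total diffuse component: uniform over ``mask``, PSF-blurred."""
    from scipy.ndimage import gaussian_filter

    n = int(mask.sum())
    if n == 0:
        return np.zeros(mask.shape)
    return gaussian_filter(mask.astype(float) / n, sigma_px, mode="constant")


def render_movie(
    history: ParticleHistory,
    geometry: CellGeometry,
    optics: OpticsConfig,
    rng_seed: int,
    frame_indices: np.ndarray | None = None,
) -> Movie:
    """Render one cell's history into a multichannel uint16 stack.

    ``frame_indices`` restricts rendering to a subset of history frames
    (e.g. only the endpoint for endpoint phenotype scoring); by default
    every recorded frame is rendered.  Deterministic per ``rng_seed``.
    """
    optics.validate()
    cfg = history.config
    rng = np.random.default_rng(rng_seed)
    if frame_indices is None:
        frame_indices = np.arange(len(history.times_h))
    frame_indices = np.asarray(frame_indices)

    H, W = optics.image_shape
    sig = optics.psf_sigma_px
    nucleus_mask, cell_mask = geometry_masks(geometry, optics)
    cyt_mask = cell_mask & ~nucleus_mask
    n_nuc_px = max(int(nucleus_mask.sum()), 1)

    nuc_fill = _blurred_fill(nucleus_mask, sig)
    cyt_fill = _blurred_fill(cyt_mask, sig)
    cell_fill = _blurred_fill(cell_mask, sig)

    channels = list(optics.channels)
    T = len(frame_indices)
    data = np.empty((T, len(channels), H, W), dtype=np.uint16)
    spot_rows = []

    cen_px = um_to_px(geometry.centrosome[None, :], optics)[0]
    disk_mean = measured_disk_mean(sig)
    F = optics.yfp_flux_per_unit
    is_cte = cfg.export_mode == "cte_mtoc"
    measured_space_spots = cfg.export_mode == "none"

    labeled = history.coats > 0
    max_count = float(2 ** optics.bit_depth - 1)

    for ti, fi in enumerate(frame_indices):
        comp = history.compartment[fi]
        pos = history.positions[fi]
        t_h = history.times_h[fi]
        free = history.free_ms2_nuclear[fi]

        expected = np.zeros((len(channels), H, W))

        for ci, ch in enumerate(channels):
            img = expected[ci]
            img += optics.autofluor_density * cell_fill * int(cell_mask.sum())

            if ch == "YFP":
                img += free * F * nuc_fill
                nuc_idx = np.nonzero((comp == NUCLEAR) & labeled)[0]
                if len(nuc_idx):
                    if measured_space_spots:
                        # reference nucleoplasm level as the measurement
                        # operators will see it (pool + cell-body baseline)
                        dens = free * F / n_nuc_px + optics.autofluor_density
                        amp = (cfg.punctae_enrichment_fold - 1.0) * dens / disk_mean
                        fluxes = np.full(len(nuc_idx), amp)
                    else:
                        fluxes = history.coats[nuc_idx] * F
                    xy = um_to_px(pos[nuc_idx], optics)
                    stamp_gaussian_spots(img, xy, fluxes, sig)
                    for (x, y), fl in zip(xy, fluxes):
                        spot_rows.append((ti, ch, x, y, fl, "nuclear"))
                out_idx = np.nonzero(
                    np.isin(comp, (CYTOPLASMIC, MT_BOUND, MTOC)) & labeled
                )[0]
                if len(out_idx):
                    fluxes = history.coats[out_idx] * F
                    xy = um_to_px(pos[out_idx], optics)
                    stamp_gaussian_spots(img, xy, fluxes, sig)
                    for (x, y), fl in zip(xy, fluxes):
                        spot_rows.append((ti, ch, x, y, fl, "cytoplasmic"))

            elif ch == "CFP":
                gag = history.gag_cytoplasm[fi] if history.gag_cytoplasm is not None else 0.0
                gag_flux = gag * optics.gag_flux_per_unit
                if is_cte and gag_flux > 0:
                    mtoc_part = optics.mtoc_gag_fraction * gag_flux
                    img += (gag_flux - mtoc_part) * cyt_fill
                    stamp_gaussian_spots(
                        img, cen_px[None, :], np.array([mtoc_part]),
                        1.5 / optics.pixel_size_um,
                    )
                else:
                    img += gag_flux * cyt_fill
                if history.vlp_appear_h is not None and len(history.vlp_appear_h):
                    vis = history.vlp_appear_h <= t_h
                    if vis.any():
                        xy = um_to_px(history.vlp_sites[vis], optics)
                        fluxes = np.full(int(vis.sum()), optics.vlp_flux)
                        stamp_gaussian_spots(img, xy, fluxes, sig)
                        for (x, y), fl in zip(xy, fluxes):
                            spot_rows.append((ti, ch, x, y, fl, "membrane"))

            elif ch == "mCherry":
                rev = history.rev_level[fi] if history.rev_level is not None else 0.0
                flux = rev * optics.rev_flux
                img += 0.6 * flux * nuc_fill + 0.4 * flux * cyt_fill

            elif ch == "DNA":
                img += optics.dna_density * n_nuc_px * nuc_fill

            elif ch == "PCNT":
                stamp_gaussian_spots(
                    img, cen_px[None, :], np.array([optics.pcnt_flux]), sig
                )
            else:
                raise ConfigurationError(f"unknown channel {ch!r}")

        lam = expected * optics.photon_scale + optics.background_level
        if optics.noiseless:
            frame = lam
        else:
            frame = rng.poisson(lam).astype(float)
            frame += rng.normal(0.0, optics.read_noise_sd, frame.shape)
        frame = np.clip(np.round(frame), 0, max_count)
        sat = (frame >= max_count).mean()
        if sat > 0.01:
            logger.warning(
                "frame %d: %.1f%% of pixels saturated", int(fi), 100 * sat
            )
        data[ti] = frame.astype(np.uint16)

    spots = pd.DataFrame(
        spot_rows, columns=["frame", "channel", "x_px", "y_px", "flux", "kind"]
    )
    return Movie(
        data=data,
        optics=optics,
        scenario=cfg.name,
        seed=rng_seed,
        times_h=history.times_h[frame_indices].copy(),
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        centrosome_px=cen_px,
        spots=spots,
    ).validate()


# ---------------------------------------------------------------------------
# OME-TIFF I/O
# ---------------------------------------------------------------------------

def write_movie(movie: Movie, path) -> Path:
    """Write ``movie`` as OME-TIFF (TCYX) + JSON sidecar + mask TIFFs."""
    movie.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stack = path / "movie.ome.tif"
    tifffile.imwrite(
        stack, movie.data, ome=True,
        metadata={"axes": "TCYX", "Channel": {"Name": list(movie.optics.channels)}},
    )
    tifffile.imwrite(path / "nucleus_mask.tif", movie.nucleus_mask.astype(np.uint8))
    tifffile.imwrite(path / "cell_mask.tif", movie.cell_mask.astype(np.uint8))
    movie.spots.to_csv(path / "spots.csv", index=False)
    sidecar = {
        "optics": movie.optics.to_dict(),
        "scenario": movie.scenario,
        "seed": int(movie.seed),
        "times_h": [float(t) for t in movie.times_h],
        "centrosome_px": [float(v) for v in movie.centrosome_px],
        "files": {
            "stack": "movie.ome.tif",
            "nucleus_mask": "nucleus_mask.tif",
            "cell_mask": "cell_mask.tif",
            "spots": "spots.csv",
        },
    }
    (path / "movie.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_movie(path) -> Movie:
    """Read a movie directory written by :func:`write_movie` (round-trips exactly)."""
    path = Path(path)
    sidecar_path = path / "movie.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar file: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    files = sidecar["files"]
    stack_path = path / files["stack"]
    if not stack_path.exists():
        raise FormatError(f"missing stack file: {stack_path}")
    data = tifffile.imread(stack_path)
    if data.ndim == 3:       # single-frame stacks drop the T axis on read
        data = data[None, ...]
    if data.ndim != 4:
        raise FormatError(f"expected a TCYX stack, got shape {data.shape}")
    optics = OpticsConfig.from_dict(sidecar["optics"])
    movie = Movie(
        data=data.astype(np.uint16),
        optics=optics,
        scenario=sidecar["scenario"],
        seed=int(sidecar["seed"]),
        times_h=np.asarray(sidecar["times_h"], dtype=float),
        nucleus_mask=tifffile.imread(path / files["nucleus_mask"]).astype(bool),
        cell_mask=tifffile.imread(path / files["cell_mask"]).astype(bool),
        centrosome_px=np.asarray(sidecar["centrosome_px"], dtype=float),
        spots=pd.read_csv(path / files["spots"]),
    )
    return movie.validate()
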