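"""Renderer tests: optics model, spot stamping, noise statistics, I/O."""

import numpy as np
import pytest

from traffiq import (
    ConfigurationError, FormatError, OpticsConfig, read_movie, render_movie,
    scenario_registry, simulate_cohort, write_movie,
)
from traffiq.pipeline import long_mode_optics
from traffiq.render import geometry_masks, stamp_gaussian_spots, um_to_px


@pytest.fixture(scope="module")
def empty_history(registry=None):
    """A cell with transcription switched off: background-only field."""
    from traffiq import scenario_registry

    cfg = scenario_registry()["dEE"].replace(k_tx=1e-6)
    return simulate_cohort(cfg, 1, 3, t_end_h=1.0, frame_interval_h=0.5)[0]


def test_optics_validation():
    with pytest.raises(ConfigurationError):
        OpticsConfig(psf_sigma_um=0.0).validate()
    with pytest.raises(ConfigurationError):
        OpticsConfig(mode="weird").validate()


def test_stamp_conserves_flux_and_subpixel_centroid():
    img = np.zeros((64, 64))
    stamp_gaussian_spots(img, np.array([[31.4, 30.7]]), np.array([5000.0]), 1.3)
    assert img.sum() == pytest.approx(5000.0, rel=1e-3)
    yy, xx = np.mgrid[0:64, 0:64]
    cx = (img * xx).sum() / img.sum()
    cy = (img * yy).sum() / img.sum()
    assert cx == pytest.approx(31.4, abs=0.01)
    assert cy == pytest.approx(30.7, abs=0.01)


def test_background_only_field_is_poisson(empty_history):
    """With no particles and no read noise, pixels follow Poisson(background)."""
    optics = long_mode_optics(
        channels=("YFP",), read_noise_sd=0.0, autofluor_density=0.0,
        background_level=100.0,
    )
    movie = render_movie(empty_history, empty_history.geometry, optics, 5)
    outside = ~movie.cell_mask
    vals = movie.data[:, 0][:, outside].astype(float)
    assert vals.mean() == pytest.approx(100.0, abs=0.5)
    assert vals.var() == pytest.approx(100.0, rel=0.1)


def test_noiseless_render_recovers_spot_centroid(registry):
    """Centroid of a rendered transcript spot lands within 0.1 px of truth."""
    cfg = registry["4xCTE"].replace(penetrance=1.0, frac_exporting=1.0)
    h = simulate_cohort(cfg, 1, 21, t_end_h=12.0, frame_interval_h=12.0,
                        )
    h = h[0]
    optics = long_mode_optics(channels=("YFP",), noiseless=True,
                              background_level=0.0, autofluor_density=0.0)
    movie = render_movie(h, h.geometry, optics, 1, frame_indices=np.array([1]))
    spots = movie.spots
    # pick an isolated cytoplasmic spot (no neighbour within 8 px)
    cand = spots[spots.kind == "cytoplasmic"]
    img = movie.data[0, 0].astype(float)
    from scipy import ndimage as ndi

    nuc_dist = ndi.distance_transform_edt(~movie.nucleus_mask)
    checked = 0
    for _, s in cand.iterrows():
        d = np.hypot(spots.x_px - s.x_px, spots.y_px - s.y_px)
        if (d < 12).sum() > 1:
            continue
        if nuc_dist[int(round(s.y_px)), int(round(s.x_px))] < 10:
            continue  # nucleoplasm-blur gradient would bias the centroid
        x0, y0 = int(round(s.x_px)), int(round(s.y_px))
        sub = img[y0 - 5:y0 + 6, x0 - 5:x0 + 6]
        yy, xx = np.mgrid[y0 - 5:y0 + 6, x0 - 5:x0 + 6]
        w = sub - sub.min()
        cx = (w * xx).sum() / w.sum()
        cy = (w * yy).sum() / w.sum()
        assert abs(cx - s.x_px) < 0.1
        assert abs(cy - s.y_px) < 0.1
        checked += 1
        if checked >= 3:
            break
    assert checked >= 1


def test_psf_conserves_photons(registry):
    """Blur redistributes intensity; the noiseless total is conserved to 0.1%."""
    cfg = registry["RRE_noRev"]
    h = simulate_cohort(cfg, 1, 9, t_end_h=4.0, frame_interval_h=4.0)[0]
    optics = long_mode_optics(channels=("YFP",), noiseless=True,
                              background_level=0.0, autofluor_density=0.0)
    movie = render_movie(h, h.geometry, optics, 1, frame_indices=np.array([1]))
    total = movie.data[0, 0].astype(float).sum()
    free = h.free_ms2_nuclear[1]
    n_spots = len(movie.spots)
    spot_flux = movie.spots.flux.sum() if n_spots else 0.0
    expected = free * optics.yfp_flux_per_unit + spot_flux
    assert total == pytest.approx(expected, rel=1e-3)


def test_rendered_nucleoplasm_monotone_in_free_pool(registry):
    """Mean nuclear YFP intensity rises with the free MS2-YFP pool."""
    cfg = registry["dEE"].replace(k_tx=1e-6)
    h = simulate_cohort(cfg, 1, 3, t_end_h=1.0, frame_interval_h=0.5)[0]
    optics = long_mode_optics(channels=("YFP",))
    means = []
    for level in (500.0, 1500.0, 2500.0):
        h.free_ms2_nuclear[:] = level
        movie = render_movie(h, h.geometry, optics, 7)
        vals = movie.data[:, 0][:, movie.nucleus_mask].mean()
        means.append(vals)
    assert means[0] < means[1] < means[2]


def test_same_seed_bit_identical_render(rendered_cell):
    h, movie = rendered_cell
    again = render_movie(h, h.geometry, movie.optics, movie.seed,
                         frame_indices=np.array([1]))
    assert np.array_equal(movie.data, again.data)


def test_write_read_roundtrip(tmp_path, registry):
    cfg = registry["RRE_Rev"]
    h = simulate_cohort(cfg, 1, 5, t_end_h=5.0, frame_interval_h=0.5)[0]
    movie = render_movie(h, h.geometry, long_mode_optics(), 9)
    write_movie(movie, tmp_path / "m")
    back = read_movie(tmp_path / "m")
    assert np.array_equal(movie.data, back.data)
    assert np.array_equal(movie.nucleus_mask, back.nucleus_mask)
    assert np.array_equal(movie.cell_mask, back.cell_mask)
    assert list(back.optics.channels) == list(movie.optics.channels)


def test_read_missing_sidecar_errors(tmp_path):
    (tmp_path / "empty").mkdir()
    with pytest.raises(FormatError) as err:
        read_movie(tmp_path / "empty")
    assert "movie.json" in str(err.value)


def test_channel_count_mismatch_errors(tmp_path, registry):
    import json

    cfg = registry["RRE_Rev"]
    h = simulate_cohort(cfg, 1, 5, t_end_h=2.0, frame_interval_h=1.0)[0]
    movie = render_movie(h, h.geometry, long_mode_optics(), 9)
    write_movie(movie, tmp_path / "m")
    sidecar = json.loads((tmp_path / "m" / "movie.json").read_text())
    sidecar["optics"]["channels"] = ["YFP"]
    (tmp_path / "m" / "movie.json").write_text(json.dumps(sidecar))
    with pytest.raises(FormatError):
        read_movie(tmp_path / "m")


def test_geometry_masks_match_analytic_areas(registry):
    cfg = registry["RRE_Rev"]
    from traffiq import make_cell_geometry

    g = make_cell_geometry(cfg, 2)
    optics = long_mode_optics()
    nuc, cell = geometry_masks(g, optics)
    px_area = optics.pixel_size_um ** 2
    assert nuc.sum() * px_area == pytest.approx(g.nucleus_area_um2(), rel=0.05)
    assert cell.sum() * px_area == pytest.approx(g.cell_area_um2(), rel=0.05)


def test_um_to_px_origin_and_axes():
    optics = long_mode_optics()
    H, W = optics.image_shape
    center = um_to_px(np.array([[0.0, 0.0]]), optics)[0]
    assert center[0] == pytest.approx(W / 2)
    assert center[1] == pytest.approx(H / 2)
    right = um_to_px(np.array([[3.25, 0.0]]), optics)[0]
    assert right[0] == pytest.approx(W / 2 + 10)
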