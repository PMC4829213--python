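"""Segmentation and measurement tests with brute-force oracles."""

import numpy as np
import pytest

from traffiq import (
    CompartmentMasks, SegmentationError, compartment_mfi, detect_punctae,
    estimate_background, make_masks, measure_movie, punctae_enrichment,
    read_movie, render_movie, scenario_registry, segment_cell, segment_nucleus,
    simulate_cohort, write_movie,
)
from traffiq.pipeline import long_mode_optics


def _iou(a, b):
    return (a & b).sum() / (a | b).sum()


# ---------------------------------------------------------------------------
# segmentation against rendered ground truth
# ---------------------------------------------------------------------------

def test_segmentation_iou_default_noise(rendered_cell):
    h, movie = rendered_cell
    masks = make_masks(movie)
    assert _iou(masks.nucleus, movie.nucleus_mask) >= 0.90
    assert _iou(masks.cell, movie.cell_mask) >= 0.85
    assert not (masks.nucleus & ~masks.cell).any()


def test_segmentation_iou_noiseless(registry):
    cfg = registry["RRE_Rev"].replace(frac_exporting=1.0, penetrance=0.0)
    h = simulate_cohort(cfg, 1, 23, t_end_h=20.0, frame_interval_h=20.0)[0]
    optics = long_mode_optics(noiseless=True)
    movie = render_movie(h, h.geometry, optics, 31, frame_indices=np.array([1]))
    masks = make_masks(movie)
    assert _iou(masks.nucleus, movie.nucleus_mask) >= 0.97


def test_segmentation_deterministic(rendered_cell):
    _, movie = rendered_cell
    m1 = make_masks(movie)
    m2 = make_masks(movie)
    assert np.array_equal(m1.nucleus, m2.nucleus)
    assert np.array_equal(m1.cell, m2.cell)


def test_no_nucleus_in_empty_frame():
    with pytest.raises(SegmentationError):
        segment_nucleus(np.zeros((128, 128)))


def test_cell_mask_contains_nucleus():
    rng = np.random.default_rng(0)
    frame = rng.poisson(100, (128, 128)).astype(float)
    yy, xx = np.mgrid[0:128, 0:128]
    nucleus = (yy - 64) ** 2 + (xx - 64) ** 2 <= 15 ** 2
    cell_true = (yy - 64) ** 2 + (xx - 64) ** 2 <= 40 ** 2
    frame[cell_true] += 40
    frame[nucleus] += 300
    cell = segment_cell(frame, nucleus)
    assert (nucleus & ~cell).sum() == 0


# ---------------------------------------------------------------------------
# background estimation
# ---------------------------------------------------------------------------

def _disk_masks(r_nuc=12, r_cell=35, shape=(128, 128)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    c = shape[0] // 2
    nucleus = (yy - c) ** 2 + (xx - c) ** 2 <= r_nuc ** 2
    cell = (yy - c) ** 2 + (xx - c) ** 2 <= r_cell ** 2
    return CompartmentMasks(nucleus=nucleus, cell=cell)


def test_background_uniform_frame():
    masks = _disk_masks()
    assert estimate_background(np.full((128, 128), 100.0), masks) == 100.0


def test_background_ignores_cell_brightness():
    masks = _disk_masks()
    frame = np.full((128, 128), 90.0)
    frame[masks.cell] = 5000.0
    assert estimate_background(frame, masks) == 90.0


def test_background_matches_bruteforce_median():
    rng = np.random.default_rng(3)
    masks = _disk_masks()
    for _ in range(5):
        frame = rng.poisson(120, (128, 128)).astype(float)
        expected = float(np.sort(frame[masks.background_annulus])[
            len(frame[masks.background_annulus]) // 2
        ]) if masks.background_annulus.sum() % 2 else float(
            np.median(frame[masks.background_annulus])
        )
        assert estimate_background(frame, masks) == pytest.approx(
            np.median(frame[masks.background_annulus])
        )


def test_background_warns_when_annulus_clipped():
    # the cell fills the field except a small notch, so fewer than 50
    # annulus pixels survive inside the image bounds
    cell = np.ones((30, 30), dtype=bool)
    cell[:6, :6] = False
    nucleus = np.zeros_like(cell)
    nucleus[12:18, 12:18] = True
    masks = CompartmentMasks(nucleus=nucleus, cell=cell)
    with pytest.warns(UserWarning):
        estimate_background(np.full((30, 30), 7.0), masks)


# ---------------------------------------------------------------------------
# compartment MFI
# ---------------------------------------------------------------------------

def test_mfi_uniform_values():
    masks = _disk_masks()
    frame = np.full((128, 128), 50.0)
    frame[masks.nucleus] = 150.0
    nuc, cyt = compartment_mfi(frame, masks, background=50.0)
    assert nuc == pytest.approx(100.0)
    assert cyt == pytest.approx(0.0)


def test_mfi_clamped_at_zero():
    masks = _disk_masks()
    frame = np.full((128, 128), 10.0)
    nuc, cyt = compartment_mfi(frame, masks, background=99.0)
    assert nuc == 0.0 and cyt == 0.0


def test_mfi_matches_bruteforce_mean():
    rng = np.random.default_rng(11)
    masks = _disk_masks()
    for _ in range(5):
        frame = rng.poisson(200, (128, 128)).astype(float)
        bg = 120.0
        nuc, cyt = compartment_mfi(frame, masks, bg)
        exp_nuc = max(frame[masks.nucleus_core()].mean() - bg, 0.0)
        exp_cyt = max(frame[masks.cytoplasm].mean() - bg, 0.0)
        assert nuc == pytest.approx(exp_nuc)
        assert cyt == pytest.approx(exp_cyt)


def test_mfi_empty_compartment_flagged():
    yy, xx = np.mgrid[0:64, 0:64]
    disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 10 ** 2
    masks = CompartmentMasks(nucleus=disk, cell=disk)   # no cytoplasm
    nuc, cyt = compartment_mfi(np.ones((64, 64)), masks, 0.0)
    assert np.isnan(cyt)


def test_mfi_affine_background_invariance():
    """Adding a constant to the frame cancels when background is re-estimated."""
    rng = np.random.default_rng(4)
    masks = _disk_masks()
    frame = rng.poisson(150, (128, 128)).astype(float)
    frame[masks.nucleus] += 200
    bg1 = estimate_background(frame, masks)
    mfi1 = compartment_mfi(frame, masks, bg1)
    shifted = frame + 77.0
    bg2 = estimate_background(shifted, masks)
    mfi2 = compartment_mfi(shifted, masks, bg2)
    assert mfi1 == pytest.approx(mfi2, abs=1e-9)


# ---------------------------------------------------------------------------
# punctae detection and enrichment
# ---------------------------------------------------------------------------

def _spotty_frame(positions, amp=400.0, base=100.0, sigma=1.23, shape=(128, 128)):
    from traffiq.render import stamp_gaussian_spots

    img = np.full(shape, base)
    flux = amp * 2 * np.pi * sigma ** 2
    stamp_gaussian_spots(img, np.asarray(positions, float),
                         np.full(len(positions), flux), sigma)
    return img


def test_detect_punctae_recovers_positions():
    masks = _disk_masks(r_nuc=40, r_cell=60)
    pts = [(50, 60), (64, 64), (80, 70), (60, 85), (75, 50)]
    rng = np.random.default_rng(8)
    img = rng.poisson(_spotty_frame(pts)).astype(float)
    spots = detect_punctae(img, masks.nucleus, "YFP", psf_sigma_px=1.23)
    assert len(spots) == 5
    for x, y in pts:
        d = min(np.hypot(s.x_px - x, s.y_px - y) for s in spots)
        assert d < 1.0


def test_detect_punctae_uniform_frame_empty():
    masks = _disk_masks(r_nuc=40)
    rng = np.random.default_rng(1)
    img = rng.poisson(100, (128, 128)).astype(float)
    assert detect_punctae(img, masks.nucleus, "YFP") == []


def test_detect_punctae_merges_subresolution_pair():
    masks = _disk_masks(r_nuc=40, r_cell=60)
    img = _spotty_frame([(64.0, 64.0), (65.0, 64.0)])
    spots = detect_punctae(img, masks.nucleus, "YFP", psf_sigma_px=1.23)
    assert len(spots) == 1


def test_enrichment_definitional_ratio():
    """Spot disk at 280 over nucleoplasm at 100 reads 2.8-fold."""
    masks = _disk_masks(r_nuc=40, r_cell=60)
    img = np.full((128, 128), 100.0)
    yy, xx = np.mgrid[0:128, 0:128]
    disk = (yy - 64) ** 2 + (xx - 64) ** 2 <= 2.46 ** 2
    img[disk] = 280.0
    from traffiq.measure import Spot

    spots = [Spot(x_px=64.0, y_px=64.0, frame=0, mfi=280.0, channel="YFP")]
    mean, sd = punctae_enrichment(spots, img, masks.nucleus, background=0.0)
    assert mean == pytest.approx(2.8, rel=0.01)


def test_enrichment_flat_disk_is_unity():
    masks = _disk_masks(r_nuc=40, r_cell=60)
    img = np.full((128, 128), 100.0)
    from traffiq.measure import Spot

    spots = [Spot(x_px=60.0, y_px=60.0, frame=0, mfi=100.0, channel="YFP")]
    mean, _ = punctae_enrichment(spots, img, masks.nucleus, background=0.0)
    assert mean == pytest.approx(1.0, rel=0.02)


def test_enrichment_scale_invariant():
    masks = _disk_masks(r_nuc=40, r_cell=60)
    rng = np.random.default_rng(2)
    img = rng.poisson(_spotty_frame([(60, 60), (75, 70)])).astype(float)
    from traffiq.measure import Spot

    spots = [Spot(60, 60, 0, 0, "YFP"), Spot(75, 70, 0, 0, "YFP")]
    m1, _ = punctae_enrichment(spots, img, masks.nucleus, background=0.0)
    m2, _ = punctae_enrichment(spots, img * 3.7, masks.nucleus, background=0.0)
    assert m1 == pytest.approx(m2, rel=1e-9)


def test_enrichment_no_spots_flagged():
    masks = _disk_masks()
    mean, sd = punctae_enrichment([], np.ones((128, 128)), masks.nucleus, 0.0)
    assert np.isnan(mean)


# ---------------------------------------------------------------------------
# whole-movie measurement and round-trip consistency
# ---------------------------------------------------------------------------

def test_measurements_survive_io_roundtrip(tmp_path, registry):
    cfg = registry["RRE_Rev"]
    h = simulate_cohort(cfg, 1, 5, t_end_h=4.0, frame_interval_h=1.0)[0]
    movie = render_movie(h, h.geometry, long_mode_optics(), 9)
    write_movie(movie, tmp_path / "m")
    back = read_movie(tmp_path / "m")
    table_a = measure_movie(movie, channels=("YFP",))
    table_b = measure_movie(back, channels=("YFP",))
    assert np.allclose(table_a["nuclear_mfi"], table_b["nuclear_mfi"])
    assert np.allclose(table_a["cytoplasmic_mfi"], table_b["cytoplasmic_mfi"])
    assert np.allclose(table_a["background"], table_b["background"])
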