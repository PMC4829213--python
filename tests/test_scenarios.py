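"""Simulator tests: geometry, trafficking dynamics, reporters, presets."""

import dataclasses

import numpy as np
import pytest

from traffiq import (
    ConfigurationError, ScenarioConfig, make_cell_geometry, scenario_registry,
    simulate_cohort, simulate_trafficking,
)
from traffiq.scenarios import (
    CYTOPLASMIC, MTOC, MT_BOUND, NUCLEAR,
    truncated_normal_matching_moments,
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "field,value",
    [
        ("export_mode", "teleport"),
        ("penetrance", 1.2),
        ("penetrance", -0.1),
        ("k_tx", -1.0),
        ("vlp_onset_min_h", 99.0),
        ("burst_threshold", 0),
        ("n_cells", 0),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = dataclasses.replace(ScenarioConfig(), **{field: value})
    with pytest.raises(ConfigurationError) as err:
        cfg.validate()
    assert field.split("_")[0] in str(err.value) or field in str(err.value)


def test_config_kv_roundtrip():
    cfg = ScenarioConfig(name="x", export_mode="burst", penetrance=0.31, k_tx=7.5)
    text = cfg.to_kv_text()
    back = ScenarioConfig.from_kv_text(text)
    assert back == cfg


def test_config_kv_rejects_unknown_key():
    with pytest.raises(ConfigurationError):
        ScenarioConfig.from_kv_text("no_such_field = 1\n")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_geometry_deterministic():
    cfg = ScenarioConfig()
    g1 = make_cell_geometry(cfg, 1)
    g2 = make_cell_geometry(cfg, 1)
    assert np.array_equal(g1.boundary_radii, g2.boundary_radii)
    assert np.array_equal(g1.centrosome, g2.centrosome)
    assert np.array_equal(g1.transcription_sites, g2.transcription_sites)


def test_geometry_invariants_over_seeds():
    cfg = ScenarioConfig()
    for seed in range(100):
        g = make_cell_geometry(cfg, seed)
        g.check_invariants()  # raises on violation
        assert g.centrosome_envelope_distance() <= 3.0
        assert all(np.allclose(t[0], g.centrosome) for t in g.mt_tracks())


def test_geometry_areas_consistent():
    g = make_cell_geometry(ScenarioConfig(), 5)
    assert 0 < g.nucleus_area_um2() < g.cell_area_um2()
    assert g.area_ratio() == pytest.approx(
        g.nucleus_area_um2() / g.cytoplasm_area_um2()
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

REQUIRED_PRESETS = {
    "dEE", "RRE_noRev", "RRE_Rev", "RRE_RevM10", "1xCTE", "4xCTE",
    "4xCTE_nocodazole", "MS2Rev_dEEgRNA", "MS2NXF1", "RevNXF1",
    "RevNXF1_NXT1", "RevM10NXF1_NXT1", "HIV_fulllength", "MPMV",
}


def test_registry_presets_complete_and_valid(registry):
    assert REQUIRED_PRESETS <= set(registry)
    for cfg in registry.values():
        cfg.validate()


def test_registry_preset_semantics(registry):
    assert registry["RRE_RevM10"].export_mode == "none"
    assert registry["4xCTE"].export_mode == "cte_mtoc"
    assert not registry["4xCTE"].nocodazole
    assert registry["4xCTE_nocodazole"].nocodazole
    assert registry["MS2Rev_dEEgRNA"].penetrance == pytest.approx(0.089)
    assert registry["RevM10NXF1_NXT1"].penetrance == pytest.approx(0.177)
    for cfg in registry.values():
        assert cfg.loops_per_transcript == 24
        assert cfg.coats_per_transcript <= 48


# ---------------------------------------------------------------------------
# trafficking dynamics
# ---------------------------------------------------------------------------

def _compartment_total(history):
    c = history.counts()
    return (
        c["nuclear"] + c["cytoplasmic"] + c["mt_bound"] + c["mtoc"] + c["degraded"]
    )


@pytest.mark.parametrize("name,seed", [
    ("RRE_Rev", 0), ("RRE_noRev", 1), ("4xCTE", 2), ("MS2Rev_dEEgRNA", 3),
])
def test_particle_conservation_exact(registry, name, seed):
    """Born particles are always in exactly one compartment."""
    h = simulate_cohort(registry[name], 2, seed, t_end_h=8.0, frame_interval_h=1.0)[0]
    born = (h.compartment != 0).sum(axis=1)
    assert np.array_equal(born, _compartment_total(h))


def test_no_export_means_zero_cytoplasmic(registry):
    h = simulate_cohort(registry["RRE_RevM10"], 2, 4, t_end_h=24.0,
                        frame_interval_h=1.0)[0]
    assert h.counts()["cytoplasmic"].max() == 0
    assert h.counts()["mt_bound"].max() == 0


def test_same_seed_bit_identical(registry):
    cfg = registry["RRE_Rev"]
    a = simulate_cohort(cfg, 2, 7, t_end_h=4.0, frame_interval_h=0.5)
    b = simulate_cohort(cfg, 2, 7, t_end_h=4.0, frame_interval_h=0.5)
    for ha, hb in zip(a, b):
        assert np.array_equal(ha.compartment, hb.compartment)
        assert np.allclose(ha.positions, hb.positions, equal_nan=True)
        assert np.array_equal(ha.free_ms2_nuclear, hb.free_ms2_nuclear)


def test_burst_crosses_threshold_then_evacuates(registry):
    """Nuclear count builds past N_burst, then drops >90% within the window."""
    cfg = registry["RRE_Rev"].replace(penetrance=1.0, frac_exporting=1.0)
    # fine cadence so the trigger crossing is visible in the recorded trace
    h = simulate_cohort(cfg, 1, 11, t_end_h=16.0, frame_interval_h=1 / 30)[0]
    nuc = h.counts()["nuclear"]
    peak_idx = int(np.argmax(nuc))
    peak = nuc[peak_idx]
    assert peak >= cfg.burst_threshold
    crossings = np.nonzero(nuc >= cfg.burst_threshold)[0]
    assert crossings[0] <= peak_idx
    window = int(np.ceil(cfg.burst_duration_h / (1 / 30)))
    after = nuc[peak_idx: peak_idx + window + 1]
    assert after.min() < 0.1 * peak


def test_nocodazole_blocks_mtoc_and_arrests_at_envelope(registry):
    noco = simulate_cohort(
        registry["4xCTE_nocodazole"].replace(penetrance=1.0, frac_exporting=1.0),
        1, 5, t_end_h=24.0, frame_interval_h=4.0,
    )[0]
    assert noco.counts()["mtoc"].max() == 0
    # arrested transcripts accumulate within 2 um of the nuclear envelope
    comp = noco.compartment[-1]
    pos = noco.positions[-1][comp == NUCLEAR]
    g = noco.geometry
    rho = g.nucleus_rho(pos[:, 0], pos[:, 1])
    a, b = g.nucleus_semiaxes
    dist_um = (1.0 - rho) * 0.5 * (a + b)
    assert np.quantile(dist_um, 0.9) <= 2.0

    active = simulate_cohort(
        registry["4xCTE"].replace(penetrance=1.0, frac_exporting=1.0),
        1, 5, t_end_h=24.0, frame_interval_h=4.0,
    )[0]
    assert active.counts()["mtoc"][-1] > 0


def test_zero_penetrance_mirrors_control(registry):
    cfg = registry["RRE_Rev"].replace(penetrance=0.0, frac_exporting=0.0)
    hs = simulate_cohort(cfg, 10, 9, t_end_h=12.0, frame_interval_h=2.0)
    for h in hs:
        assert not h.program.hallmark
        assert h.counts()["cytoplasmic"].max() == 0


def test_cytoplasmic_msd_matches_diffusion_coefficient(registry):
    """Ground-truth cytoplasmic MSD slope recovers 4*D within 10%."""
    cfg = registry["4xCTE"].replace(
        export_mode="gradual", penetrance=1.0, frac_exporting=1.0,
        cell_radius_um=30.0, cell_radius_sd_um=0.1,
        nucleus_semiaxes_um=(5.0, 4.0),
    )
    dt = 0.7 / 3600.0
    hs = simulate_cohort(
        cfg, 3, 13, t_end_h=40 * dt, frame_interval_h=dt,
        n_initial_cyt=80, dt_h=dt / 2,
    )
    disps = []
    for h in hs:
        cyt_all = (h.compartment == CYTOPLASMIC).all(axis=0)
        p = h.positions[:, cyt_all]      # (T, n, 2)
        for lag in (1, 2, 3):
            d = p[lag:] - p[:-lag]
            disps.append((lag, np.nanmean(d[..., 0] ** 2 + d[..., 1] ** 2)))
    lags = np.array([l for l, _ in disps], dtype=float)
    msd = np.array([m for _, m in disps])
    slope = np.polyfit(lags * 0.7, msd, 1)[0]
    assert slope == pytest.approx(4 * cfg.d_cyt_um2_s, rel=0.10)


def test_mt_step_displacement_matches_speed(registry):
    """Noiseless ground truth: per-step along-track motion equals v*dt."""
    cfg = registry["4xCTE"].replace(
        penetrance=1.0, frac_exporting=1.0, mt_run_length_um=5.0,
        mtoc_capture_radius_um=0.3,
    )
    dt = 0.7 / 3600.0
    hs = simulate_cohort(
        cfg, 3, 19, t_end_h=80 * dt, frame_interval_h=dt,
        n_initial_cyt=40, dt_h=dt,
    )
    steps = []
    for h in hs:
        cen = h.geometry.centrosome
        on_mt = h.compartment == MT_BOUND
        r = np.hypot(h.positions[..., 0] - cen[0], h.positions[..., 1] - cen[1])
        both = on_mt[1:] & on_mt[:-1]
        dr = np.abs(r[1:] - r[:-1])[both]
        steps.extend(dr.tolist())
    v_step = cfg.mt_speed_um_s * 0.7
    assert np.mean(steps) == pytest.approx(v_step, rel=0.05)


def test_free_pool_accounting(registry, rre_rev_history):
    """free = Y_tot - coats * labeled transcripts born, never negative."""
    h = rre_rev_history
    cfg = h.config
    lab_born = (h.coats > 0) & (h.compartment != 0)
    expected = np.maximum(
        cfg.ms2_pool_units - cfg.coats_per_transcript * lab_born.sum(axis=1), 0
    )
    assert np.allclose(h.free_ms2_nuclear, expected)
    assert (h.free_ms2_nuclear >= 0).all()


def test_compartment_transitions_follow_allowed_edges(registry):
    cfg = registry["4xCTE"].replace(penetrance=1.0, frac_exporting=1.0)
    h = simulate_cohort(cfg, 2, 3, t_end_h=12.0, frame_interval_h=0.25)[0]
    # frame-sampled transitions are compositions of the allowed internal
    # edges; the invariants visible at any sampling are irreversibility of
    # birth, export and degradation
    trans = set()
    for j in range(h.compartment.shape[1]):
        col = h.compartment[:, j]
        changes = np.nonzero(np.diff(col) != 0)[0]
        for i in changes:
            trans.add((int(col[i]), int(col[i + 1])))
    for src, dst in trans:
        assert dst != 0, "nothing returns to unborn"
        assert dst != NUCLEAR or src == 0, "export is irreversible"
        assert src != 5, "degradation is terminal"


# ---------------------------------------------------------------------------
# reporters
# ---------------------------------------------------------------------------

def test_gag_zero_without_cytoplasmic_particles(registry):
    h = simulate_cohort(registry["dEE"], 1, 2, t_end_h=24.0, frame_interval_h=1.0)[0]
    assert np.all(h.gag_cytoplasm == 0)
    assert np.all(h.membrane_punctae == 0)


def test_gag_linear_accumulation(registry, rre_rev_history):
    """Gag increments by k_translate * cytoplasmic count * dt each frame."""
    from traffiq.scenarios import simulate_reporters

    h = rre_rev_history
    cfg = h.config
    in_cyt = np.isin(h.compartment, (CYTOPLASMIC, MT_BOUND, MTOC))
    n_cyt = in_cyt.sum(axis=1).astype(float)
    dt = np.diff(h.times_h, prepend=h.times_h[0])
    expected = np.cumsum(cfg.k_translate * n_cyt * dt)
    assert np.allclose(h.gag_cytoplasm, expected)


def test_vlp_never_before_minimum(registry):
    cfg = registry["4xCTE"].replace(frac_exporting=1.0, penetrance=1.0)
    hs = simulate_cohort(cfg, 30, 6, t_end_h=10.0, frame_interval_h=1.0)
    for h in hs:
        assert h.program.vlp_onset_h >= cfg.vlp_onset_min_h
        on = np.nonzero(h.membrane_punctae > 0)[0]
        if len(on):
            assert h.times_h[on[0]] >= cfg.vlp_onset_min_h


def test_rev_level_zero_then_monotone(registry, rre_rev_history):
    h = rre_rev_history
    before = h.times_h < h.program.rev_onset_h
    assert np.all(h.rev_level[before] == 0)
    assert np.all(np.diff(h.rev_level) >= 0)


# ---------------------------------------------------------------------------
# distribution helper
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mean,sd,lo", [(16.7, 8.06, 5.0), (20.3, 8.07, 5.0)])
def test_truncated_normal_matches_published_moments(mean, sd, lo):
    d = truncated_normal_matching_moments(mean, sd, lo)
    assert d.mean() == pytest.approx(mean, abs=0.05)
    assert d.std() == pytest.approx(sd, abs=0.05)
    assert d.ppf(0.0001) >= lo
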