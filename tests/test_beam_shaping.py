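"""Unit and property tests for mask design, propagation and targets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boecyto import beam_shaping as bs
from boecyto.field import ComplexField, GridSpec


# ---------------------------------------------------------------------------
# focal sampling interval and relief arithmetic


def test_focal_sampling_interval_reference_design(paper_optics):
    """488 nm, f = 10 mm, D = 3 mm puts focal samples 1.63 um apart."""
    interval = bs.focal_sampling_interval(paper_optics)
    assert interval == pytest.approx(1.63e-6, rel=5e-3)


def test_focal_sampling_interval_scales_linearly_with_f(paper_optics):
    f100 = bs.OpticalConfig(focal_length=100e-3)
    assert bs.focal_sampling_interval(f100) == pytest.approx(
        10 * bs.focal_sampling_interval(paper_optics)
    )
    f20 = bs.OpticalConfig(focal_length=20e-3)
    assert bs.focal_sampling_interval(f20) == pytest.approx(
        2 * bs.focal_sampling_interval(paper_optics)
    )


def test_invalid_optical_config_rejected():
    with pytest.raises(bs.InvalidConfigError):
        bs.OpticalConfig(wavelength=-1.0)
    with pytest.raises(bs.InvalidConfigError):
        bs.OpticalConfig(phase_levels=12)  # not a power of two
    with pytest.raises(bs.InvalidConfigError):
        bs.OpticalConfig(refractive_index=0.9)


def test_relief_height_step_and_values(paper_optics):
    """16-level quartz mask at 488 nm etches in ~66 nm steps; h = lam*phi/2pi(n-1)."""
    mask = bs.PhaseMask(np.array([[0.0, np.pi]]), paper_optics.zone_pitch)
    relief = bs.phase_to_relief(mask, paper_optics)
    assert round(relief.height_step * 1e9) == 66
    assert relief.height[0, 0] == 0.0
    # phi = pi: h = 488/(2*0.4632) nm
    assert relief.height[0, 1] == pytest.approx(526.7e-9, rel=1e-3)


def test_relief_of_quantized_mask_has_at_most_levels_values(rng):
    mask = bs.PhaseMask(rng.uniform(0, 2 * np.pi, (32, 32)), 1e-5)
    q = bs.quantize_phase(mask, 16)
    relief = bs.phase_to_relief(q, bs.OpticalConfig())
    assert len(np.unique(np.round(relief.height / relief.height_step))) <= 16


# ---------------------------------------------------------------------------
# quantization


def test_quantize_sixteen_levels_interval():
    mask = bs.PhaseMask(np.array([[np.pi / 3]]), 1e-5)
    q = bs.quantize_phase(mask, 16)
    # pi/3 is nearer 3pi/8 than 2pi/8
    assert q.phase[0, 0] == pytest.approx(3 * np.pi / 8)
    assert q.levels == 16


def test_quantize_midpoint_rounds_down():
    step = 2 * np.pi / 16
    mask = bs.PhaseMask(np.array([[1.5 * step]]), 1e-5)
    assert bs.quantize_phase(mask, 16).phase[0, 0] == pytest.approx(step)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    phases=st.lists(st.floats(0, 2 * np.pi, exclude_max=True), min_size=1, max_size=16),
    levels_exp=st.integers(1, 6),
)
def test_quantize_idempotent_and_on_grid(phases, levels_exp):
    levels = 2**levels_exp
    mask = bs.PhaseMask(np.array(phases), 1e-5)
    q1 = bs.quantize_phase(mask, levels)
    q2 = bs.quantize_phase(q1, levels)
    assert np.array_equal(q1.phase, q2.phase)
    k = q1.phase / (2 * np.pi / levels)
    assert np.allclose(k, np.round(k))
    assert np.all((q1.phase >= 0) & (q1.phase < 2 * np.pi))


def test_quantize_rejects_degenerate_levels():
    mask = bs.PhaseMask(np.zeros((2, 2)), 1e-5)
    with pytest.raises(ValueError):
        bs.quantize_phase(mask, 1)


# ---------------------------------------------------------------------------
# targets


def test_r1_target_area(paper_optics):
    """Coverage-weighted raster carries the exact 50x10 um = 500 um^2 area."""
    target = bs.make_target("R1", bs.focal_grid_for(paper_optics))
    assert target.region_area() * 1e12 == pytest.approx(500.0, rel=1e-9)


def test_r2_leading_edge_separation(paper_optics):
    target = bs.make_target("R2", bs.focal_grid_for(paper_optics))
    leading = sorted(r.center_y - r.height / 2 for r in target.geometry)
    assert (leading[1] - leading[0]) == pytest.approx(110e-6)


def test_r3_target_area(paper_optics):
    target = bs.make_target("R3", bs.focal_grid_for(paper_optics))
    assert target.region_area() * 1e12 == pytest.approx(3500.0, rel=1e-9)


def test_target_amplitude_unit_energy_and_support(paper_optics):
    target = bs.make_target("R3", bs.focal_grid_for(paper_optics))
    energy = np.sum(target.amplitude**2) * target.sample_pitch**2
    assert energy == pytest.approx(1.0, rel=1e-12)
    assert not np.any(target.amplitude[~target.signal_region])


def test_target_exceeding_grid_raises():
    grid = GridSpec(64, 1e-6)
    with pytest.raises(bs.ExtentError):
        bs.make_target("custom", grid, [bs.Rect(0, 0, 100e-6, 10e-6)])


def test_target_too_coarse_grid_raises():
    with pytest.raises(ValueError, match="coarse"):
        bs.make_target("custom", GridSpec(64, 8e-6), [bs.Rect(0, 0, 50e-6, 10e-6)])


# ---------------------------------------------------------------------------
# propagation


@pytest.mark.parametrize("zones,pad", [(16, 2), (32, 2), (32, 4), (64, 4)])
def test_propagation_conserves_energy(zones, pad, rng):
    cfg = bs.OpticalConfig(zones_per_side=zones, pad_factor=pad)
    phase = rng.uniform(0, 2 * np.pi, (zones, zones))
    ap = bs.aperture_field(cfg, phase=phase)
    focal = bs.propagate_to_focal(ap, cfg)
    assert focal.energy() == pytest.approx(ap.energy(), rel=1e-10)


def test_zero_field_propagates_to_zero(toy_optics):
    ap = ComplexField(np.zeros((64, 64)), toy_optics.sample_pitch, "aperture")
    focal = bs.propagate_to_focal(ap, toy_optics)
    assert np.all(focal.values == 0)


def _brute_force_focal(field: ComplexField, cfg: bs.OpticalConfig) -> np.ndarray:
    """Direct double-sum evaluation of the scaled Fourier integral."""
    n = field.n
    lam_f = cfg.wavelength * cfg.focal_length
    idx = np.arange(n) - n // 2
    out = np.zeros((n, n), dtype=complex)
    for p in range(n):
        for q in range(n):
            # rows index y/v, columns index x/u, matching the fast transform
            phase = np.exp(
                -2j * np.pi * (idx[p] * idx[:, None] + idx[q] * idx[None, :]) / n
            )
            out[p, q] = np.sum(field.values * phase) * field.sample_pitch**2 / lam_f
    return out


def test_fast_propagation_matches_brute_force_dft(rng):
    """Scaled FFT equals the explicit double-sum transform on a 16x16 grid."""
    cfg = bs.OpticalConfig(zones_per_side=16, pad_factor=1)
    vals = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
    ap = ComplexField(vals, cfg.sample_pitch, "aperture")
    fast = bs.propagate_to_focal(ap, cfg).values
    slow = _brute_force_focal(ap, cfg)
    assert np.max(np.abs(fast - slow)) / np.max(np.abs(slow)) < 1e-8


def test_uniform_square_aperture_gives_centered_sinc_lobe():
    cfg = bs.OpticalConfig(zones_per_side=16, pad_factor=4)
    ap = bs.aperture_field(cfg)
    inten = bs.propagate_to_focal(ap, cfg).intensity()
    c = cfg.grid_n // 2
    assert np.unravel_index(np.argmax(inten), inten.shape) == (c, c)
    # separable sinc^2: symmetric about the axis
    assert inten[c, c + 5] == pytest.approx(inten[c, c - 5], rel=1e-9)
    assert inten[c + 5, c] == pytest.approx(inten[c - 5, c], rel=1e-9)


def test_round_trip_propagation_is_identity(toy_optics, rng):
    phase = rng.uniform(0, 2 * np.pi, (32, 32))
    ap = bs.aperture_field(toy_optics, phase=phase)
    back = bs.propagate_to_aperture(
        bs.propagate_to_focal(ap, toy_optics), toy_optics
    )
    assert np.allclose(back.values, ap.values, atol=1e-12)


# ---------------------------------------------------------------------------
# Gerchberg-Saxton design


@pytest.fixture(scope="module")
def toy_bar_target(toy_optics):
    grid = bs.focal_grid_for(toy_optics)
    return bs.make_target(
        "custom", grid, [bs.Rect(0.0, 0.0, 20 * grid.pitch, 4 * grid.pitch)]
    )


def test_gs_plain_projection_error_is_monotone(toy_optics, toy_bar_target):
    """Without feedback or quantization the signal-region amplitude mismatch
    never increases (classical error-reduction property)."""
    opts = bs.GSOptions(
        free_iterations=40, stage_levels=(), feedback_strength=0.0,
        convergence_tol=1e-15,
    )
    _, _, log = bs.gs_design(toy_bar_target, toy_optics, opts)
    mism = log.history[log.history.levels == 0]["mismatch"].to_numpy()
    assert np.all(np.diff(mism) <= 1e-12)


def test_gs_improves_uniformity_and_delivers_energy(toy_optics, toy_bar_target):
    _, _, log = bs.gs_design(toy_bar_target, toy_optics, bs.GSOptions(free_iterations=40))
    hist = log.history
    assert hist["rmsi"].iloc[-1] <= hist["rmsi"].iloc[0]
    assert hist["eta"].iloc[-1] > 0


def test_gs_deterministic_given_seed(toy_optics, toy_bar_target):
    opts = bs.GSOptions(rng_seed=7, free_iterations=10, stage_levels=(16,), stage_iterations=3)
    mask1, focal1, _ = bs.gs_design(toy_bar_target, toy_optics, opts)
    mask2, focal2, _ = bs.gs_design(toy_bar_target, toy_optics, opts)
    assert np.array_equal(mask1.phase, mask2.phase)
    assert np.array_equal(focal1.values, focal2.values)


def test_gs_fixed_point_of_reachable_target(toy_optics):
    """A target equal to the flat-aperture focal amplitude is a fixed point:
    the mismatch is ~0 from the first iteration with a zero initial phase."""
    ap = bs.aperture_field(toy_optics)
    focal = bs.propagate_to_focal(ap, toy_optics)
    amp = focal.amplitude()
    energy = np.sum(amp**2) * focal.sample_pitch**2
    target = bs.TargetSpot(
        spot_kind="custom",
        amplitude=amp / np.sqrt(energy),
        signal_region=np.ones_like(amp, dtype=bool),
        coverage=(amp > 0).astype(float),
        geometry=(bs.Rect(0, 0, 1e-5, 1e-5),),
        sample_pitch=focal.sample_pitch,
    )
    opts = bs.GSOptions(
        initial_phase="zero", free_iterations=2, stage_levels=(), feedback_strength=0.0
    )
    _, _, log = bs.gs_design(target, toy_optics, opts)
    assert log.history["mismatch"].iloc[:2].max() < 1e-12


def test_gs_returns_mask_quantized_to_config_levels(toy_optics, toy_bar_target):
    opts = bs.GSOptions(free_iterations=5, stage_levels=(16,), stage_iterations=2)
    mask, _, _ = bs.gs_design(toy_bar_target, toy_optics, opts)
    assert mask.quantized and mask.levels == toy_optics.phase_levels
    k = mask.phase / (2 * np.pi / mask.levels)
    assert np.allclose(k, np.round(k))
    assert mask.phase.shape == (toy_optics.zones_per_side,) * 2


def test_gs_rejects_target_on_wrong_grid(toy_optics):
    grid = GridSpec(32, 1e-6)
    target = bs.make_target("custom", grid, [bs.Rect(0, 0, 8e-6, 4e-6)])
    with pytest.raises(bs.InvalidConfigError):
        bs.gs_design(target, toy_optics, bs.GSOptions(free_iterations=2))
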