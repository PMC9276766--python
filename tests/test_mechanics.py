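"""Kymographs, center of expansion, boundary motion, pressure-density model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tissellate as tl
from tissellate.mechanics import FieldMovie, Kymograph


def make_movie(profile, nt=10, ny=30, noise=0.0, seed=0, window=88.0, kind="v_x"):
    """FieldMovie whose every frame equals a given x-profile (plus noise)."""
    x = np.arange(len(profile)) * window + window / 2
    y = np.arange(ny) * window + window / 2
    t = np.arange(nt) / 3
    values = np.tile(np.asarray(profile, float), (nt, ny, 1))
    if noise:
        values = values + noise * np.random.default_rng(seed).standard_normal(values.shape)
    return FieldMovie(values, x, y, t, kind=kind, window_um=window)


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

def test_uniform_field_gives_constant_kymograph():
    movie = make_movie(np.full(40, 7.5), ny=40)
    kymo = tl.build_kymograph(movie, band_margin=1000.0)
    assert np.allclose(kymo.values, 7.5)
    assert kymo.values.shape == (40, 10)


def test_linear_profile_reproduced_per_timepoint():
    x = np.arange(40) * 88.0 + 44.0
    movie = make_movie(0.01 * x, ny=40)
    kymo = tl.build_kymograph(movie, band_margin=500.0, time_smooth=1)
    assert np.allclose(kymo.values, np.tile(0.01 * x, (10, 1)).T)


def test_band_average_suppresses_noise():
    """Averaging n rows reduces white noise by ~1/sqrt(n)."""
    profile = np.zeros(30)
    movie = make_movie(profile, nt=6, ny=46, noise=1.0, seed=3)
    kymo = tl.build_kymograph(movie, band_margin=1000.0, time_smooth=1)
    n_rows = 46 - 2 * int(1000 / 88)
    assert np.abs(kymo.values).max() < 5.0 / np.sqrt(n_rows)


def test_margin_larger_than_field_rejected():
    movie = make_movie(np.zeros(10), ny=10)
    with pytest.raises(ValueError, match="band_margin"):
        tl.build_kymograph(movie, band_margin=2000.0)


def test_empty_bins_stay_nan():
    movie = make_movie(np.zeros(10), ny=12)
    movie.values[:, :, 3] = np.nan
    kymo = tl.build_kymograph(movie, band_margin=100.0, time_smooth=1)
    assert np.isnan(kymo.values[3]).all()


def test_average_identical_kymographs_is_identity():
    movie = make_movie(np.sin(np.arange(20)), ny=30)
    kymo = tl.build_kymograph(movie, band_margin=500.0)
    mean = tl.average_kymographs([kymo, kymo, kymo])
    assert np.allclose(mean.values, kymo.values, equal_nan=True)


def test_opposite_kymographs_cancel():
    movie = make_movie(np.linspace(-5, 5, 20), ny=30)
    kymo = tl.build_kymograph(movie, band_margin=500.0)
    neg = Kymograph(-kymo.values, kymo.x_um, kymo.t_h, kymo.kind, kymo.bin_um)
    mean = tl.average_kymographs([kymo, neg])
    assert np.allclose(mean.values, 0.0)


def test_average_of_noisy_replicates_shrinks_residual():
    """Five sigma=1 replicates leave ~1/sqrt(5) residual RMS."""
    template = np.sin(np.arange(30) / 4)
    kymos = []
    for seed in range(5):
        movie = make_movie(template, nt=8, ny=12, noise=1.0, seed=seed)
        kymos.append(tl.build_kymograph(movie, band_margin=100.0, time_smooth=1))
    mean = tl.average_kymographs(kymos)
    clean = tl.build_kymograph(make_movie(template, nt=8, ny=12),
                               band_margin=100.0, time_smooth=1)
    resid = mean.values - clean.values
    rms = np.sqrt(np.nanmean(resid ** 2))
    n_rows = 12 - 2 * int(100 / 88)
    expected = 1.0 / np.sqrt(5 * n_rows)
    assert rms == pytest.approx(expected, rel=0.5)


def test_incompatible_binning_rejected():
    movie = make_movie(np.zeros(20), ny=30)
    a = tl.build_kymograph(movie, band_margin=500.0)
    b = tl.build_kymograph(movie, band_margin=500.0, bin_um=176.0)
    with pytest.raises(ValueError, match="binning"):
        tl.average_kymographs([a, b])


# ---------------------------------------------------------------------------
# center of expansion
# ---------------------------------------------------------------------------

def test_divergent_flow_center_recovered():
    """v_x = alpha (x - x_c) puts the center at x_c within half a bin."""
    x = np.arange(60) * 88.0 + 44.0
    x_c = x[33]
    movie = make_movie(0.05 * (x - x_c), ny=30)
    kymo = tl.build_kymograph(movie, band_margin=500.0)
    trace = tl.center_of_expansion(kymo, threshold=3.0)
    assert np.all(np.abs(trace - x_c) <= 44.0)


def test_no_slow_bin_gives_missing_value():
    movie = make_movie(np.full(20, 10.0), ny=30)
    kymo = tl.build_kymograph(movie, band_margin=500.0)
    assert np.isnan(tl.center_of_expansion(kymo, threshold=3.0)).all()


def test_largest_contiguous_run_wins():
    profile = np.full(30, 10.0)
    profile[4:6] = 0.0     # short spurious slow region
    profile[15:25] = 0.0   # the real plateau
    movie = make_movie(profile, ny=30)
    kymo = tl.build_kymograph(movie, band_margin=500.0, time_smooth=1)
    trace = tl.center_of_expansion(kymo)
    mid = (kymo.x_um[15] + kymo.x_um[24]) / 2
    assert np.allclose(trace, mid)


# ---------------------------------------------------------------------------
# boundary velocity
# ---------------------------------------------------------------------------

def make_trace(x_of_t, t=None):
    t = np.arange(0, 48, 1 / 3) if t is None else t
    return tl.BoundaryTrace(t, x_of_t(t), x0=float(x_of_t(t)[0]),
                            t_fuse=float(t[0]), x_fuse=float(x_of_t(t)[0]))


def test_static_boundary_zero_velocity():
    trace = make_trace(lambda t: np.full(t.size, 3000.0))
    assert tl.boundary_velocity(trace) == 0.0


def test_linear_drift_recovered_exactly():
    trace = make_trace(lambda t: 3000.0 + 10.0 * t)
    assert tl.boundary_velocity(trace) == pytest.approx(10.0, rel=1e-12)


def test_noisy_drift_recovered():
    rng = np.random.default_rng(5)
    trace = make_trace(lambda t: 3000.0 + 8.0 * t + 5.0 * rng.standard_normal(t.size))
    assert tl.boundary_velocity(trace) == pytest.approx(8.0, abs=1.0)


def test_too_few_points_rejected():
    trace = make_trace(lambda t: 3000.0 + t, t=np.array([1.0, 2.0, 30.0]))
    with pytest.raises(ValueError, match="at least 3"):
        tl.boundary_velocity(trace, window=(20, 36))


# ---------------------------------------------------------------------------
# density from nuclei
# ---------------------------------------------------------------------------

def test_poisson_pattern_mean_density_recovered():
    rng = np.random.default_rng(11)
    n = rng.poisson(2000 * 4.0)  # 2000 cells/mm^2 over 4 mm^2
    pts = pd.DataFrame({
        "x_um": rng.uniform(0, 2000, n),
        "y_um": rng.uniform(0, 2000, n),
    })
    movie = tl.density_from_nuclei(pts, extent=(2000, 2000), window_um=100.0)
    assert movie.values.mean() == pytest.approx(2000, abs=50)


def test_empty_table_gives_zero_field():
    movie = tl.density_from_nuclei(pd.DataFrame(columns=["x_um", "y_um"]),
                                   extent=(880, 880))
    assert not movie.values.any()


def test_single_point_single_window_density():
    pts = pd.DataFrame({"x_um": [44.0], "y_um": [44.0]})
    movie = tl.density_from_nuclei(pts, extent=(88, 88), window_um=88.0)
    assert movie.values[0, 0, 0] == pytest.approx(1 / 0.088 ** 2, rel=1e-6)
    assert movie.values[0, 0, 0] == pytest.approx(129.1, abs=0.1)


# ---------------------------------------------------------------------------
# density gradient at boundary
# ---------------------------------------------------------------------------

def test_uniform_density_zero_gradient():
    movie = make_movie(np.full(40, 2200.0), ny=20, kind="density")
    assert tl.density_gradient_at_boundary(movie, 1760.0) == pytest.approx(0.0)


def test_linear_profile_gradient_exact():
    x = np.arange(40) * 88.0 + 44.0
    movie = make_movie(1000 + 2.0 * x, ny=20, kind="density")
    xb = 88.0 * 20  # on a window edge so the side boxes tile symmetrically
    grad = tl.density_gradient_at_boundary(movie, xb, width=88.0 * 4)
    assert grad == pytest.approx(2.0, rel=1e-9)


def test_step_profile_matches_seeding_mismatch_arithmetic():
    """2600 | 1800 cells/mm^2 across the boundary: (1800-2600)/300."""
    profile = np.where(np.arange(40) < 20, 2600.0, 1800.0)
    movie = make_movie(profile, ny=20, kind="density", window=75.0)
    xb = 20 * 75.0
    grad = tl.density_gradient_at_boundary(movie, xb, width=300.0)
    assert grad == pytest.approx((1800 - 2600) / 300, rel=1e-9)
    assert grad == pytest.approx(-2.67, abs=0.01)


def test_side_region_outside_data_rejected():
    movie = make_movie(np.full(10, 2000.0), ny=20, kind="density")
    with pytest.raises(ValueError, match="outside"):
        tl.density_gradient_at_boundary(movie, 100.0, width=300.0)


# ---------------------------------------------------------------------------
# pressure-velocity relation
# ---------------------------------------------------------------------------

def test_pressure_velocity_unit_chain():
    """P' = 0.5 Pa mm^2, xi = 100 Pa s/um^2, grad = -2.67 -> ~+48 um/h."""
    v = tl.pressure_velocity(-8.0 / 3.0, p_prime=0.5, xi=100.0)
    assert v == pytest.approx(48.0, rel=1e-9)
    # dimensional audit: without the s->h factor the same chain is um/s
    assert v / 3600 == pytest.approx(0.5 / 100 * 8.0 / 3.0, rel=1e-9)


def test_zero_gradient_zero_velocity():
    assert tl.pressure_velocity(0.0) == 0.0


def test_velocity_linear_in_p_prime():
    v1 = tl.pressure_velocity(-1.5, p_prime=0.5)
    v2 = tl.pressure_velocity(-1.5, p_prime=1.0)
    assert v2 == pytest.approx(2 * v1)


def test_nonpositive_friction_rejected():
    with pytest.raises(ValueError, match="xi"):
        tl.pressure_velocity(-1.0, xi=0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(grad=st.floats(-5.0, 5.0), p_prime=st.floats(0.01, 5.0),
       xi=st.floats(1.0, 1000.0))
def test_boundary_always_moves_down_gradient(grad, p_prime, xi):
    v = tl.pressure_velocity(grad, p_prime, xi)
    assert v * grad <= 0  # opposite signs (or both zero)


# ---------------------------------------------------------------------------
# slope fit and moduli
# ---------------------------------------------------------------------------

def test_noiseless_pairs_invert_exactly():
    pairs = tl.synth_velocity_density_pairs(p_prime=0.7, xi=120.0, n=10,
                                            noise_frac=0.0, seed=3)
    fit = tl.fit_pressure_slope(pairs["drho_dx"], pairs["v_boundary"], xi=120.0)
    assert fit.p_prime == pytest.approx(0.7, rel=1e-9)
    assert fit.intercept == pytest.approx(0.0, abs=1e-9)


def test_degenerate_gradients_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        tl.fit_pressure_slope([-1.0, -1.0, -1.0], [5.0, 6.0, 7.0])


def test_noisy_pairs_recover_p_prime_within_20_percent():
    pairs = tl.synth_velocity_density_pairs(p_prime=0.5, xi=100.0, n=25,
                                            noise_frac=0.1, seed=0)
    fit = tl.fit_pressure_slope(pairs["drho_dx"], pairs["v_boundary"], xi=100.0)
    assert fit.p_prime == pytest.approx(0.5, rel=0.2)
    assert fit.r < -0.9


def test_fit_through_assay_averages():
    """The line goes through assay means; r is over individual pairs."""
    g = np.array([-1.0, -1.2, -2.0, -2.4])
    v = tl.pressure_velocity(g)
    assay = ["a", "a", "b", "b"]
    fit = tl.fit_pressure_slope(g, v + [1, -1, 2, -2], assay=assay)
    means_g = np.array([-1.1, -2.2])
    means_v = np.array([(v[0] + 1 + v[1] - 1) / 2, (v[2] + 2 + v[3] - 2) / 2])
    expected_slope = np.diff(means_v)[0] / np.diff(means_g)[0]
    assert fit.slope == pytest.approx(expected_slope, rel=1e-9)
    assert fit.n_assays == 2 and fit.n_pairs == 4


def test_through_origin_option():
    g = np.array([-2.0, -1.0, -0.5])
    v = -18.0 * g + 3.0
    fit = tl.fit_pressure_slope(g, v, through_origin=True)
    assert fit.intercept == 0.0


def test_bulk_modulus_chain_gives_about_2_kpa():
    """K = P' rho: 0.5 Pa mm^2 x 3.4e3 mm^-2 = 1.7 kPa ~ 2 kPa."""
    k = tl.bulk_modulus(0.5, 3.4e3)
    assert k == pytest.approx(1700.0, rel=1e-12)
    assert round(k / 1000, 0) == 2  # one significant figure


def test_bulk_modulus_linear_in_density():
    assert tl.bulk_modulus(0.5, 6.8e3) == pytest.approx(2 * tl.bulk_modulus(0.5, 3.4e3))
    assert tl.bulk_modulus(0.0, 1000.0) == 0.0
    with pytest.raises(ValueError):
        tl.bulk_modulus(0.5, -1.0)


def test_eos_reference_density_and_log_slope():
    assert tl.eos_pressure(2000.0, K=1700.0, rho_e=2000.0) == 0.0
    assert tl.eos_pressure(np.e * 2000.0, K=1700.0, rho_e=2000.0) == pytest.approx(1700.0)
    rho = 3000.0
    h = 1e-3
    fd = (tl.eos_pressure(rho + h, 1700.0, 2000.0)
          - tl.eos_pressure(rho - h, 1700.0, 2000.0)) / (2 * h)
    assert fd == pytest.approx(1700.0 / rho, rel=1e-6)
    with pytest.raises(ValueError):
        tl.eos_pressure(-5.0, 1700.0, 2000.0)


def test_monolayer_stiffness_conversion():
    """Gamma = 2.4 mN/m over h = 5 um converts to E = 0.48 kPa."""
    assert tl.stiffness_from_tension(2.4, 5.0) == pytest.approx(0.48, rel=1e-12)
    assert tl.stiffness_from_tension(0.0, 5.0) == 0.0
    assert tl.stiffness_from_tension(2.4, 10.0) == pytest.approx(0.24)
    with pytest.raises(ValueError):
        tl.stiffness_from_tension(2.4, 0.0)
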