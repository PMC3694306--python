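import numpy as np
import pytest
from scipy.signal import find_peaks

from peldock import deer
from peldock.labeling import DistanceDistribution
from peldock.synthetic import make_distribution

R_GRID = np.arange(15.0, 80.5, 0.5)
T_GRID = deer.default_time_grid()


def _form_trace(P, noise_sd=0.0, seed=0):
    """Noiseless/noisy form factor trace for a known distribution."""
    F = deer.dipolar_kernel(T_GRID, P.r) @ (P.p * np.gradient(P.r))
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, T_GRID.size)
    return deer.DeerTrace(T_GRID, F)


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

def test_dipolar_constant_from_physical_constants():
    assert abs(deer.DIPOLAR_CONSTANT_MHZ_NM3 - 52.04) < 0.01


def test_kernel_normalization_and_bounds():
    K = deer.dipolar_kernel(T_GRID[:64], R_GRID[::8])
    np.testing.assert_allclose(K[0], 1.0, atol=1e-9)
    assert np.all(np.abs(K) <= 1.0 + 1e-12)


def test_kernel_rejects_invalid_grids():
    with pytest.raises(ValueError):
        deer.dipolar_kernel(T_GRID[:8], np.array([-1.0, 20.0]))
    with pytest.raises(ValueError):
        deer.dipolar_kernel(np.array([0.0, np.nan]), np.array([20.0]))


def test_pake_turning_point_single_distance():
    # nu_perp = D / r^3: 6.5 MHz at 20 A
    P = make_distribution("gaussian", {"mean": 20.0, "fwhm": 0.7}, R_GRID)
    freq, spec = deer.pake_spectrum(_form_trace(P))
    sel = freq > 2.0
    nu_peak = freq[sel][np.argmax(spec[sel])]
    nu_expected = deer.DIPOLAR_CONSTANT_MHZ_NM3 / 2.0**3
    assert abs(nu_peak - nu_expected) < 0.3


def test_long_distance_column_varies_slower():
    K = deer.dipolar_kernel(T_GRID, np.array([20.0, 80.0]))

    def first_zero_crossing(col):
        sign = np.signbit(col)
        idx = np.flatnonzero(np.diff(sign))
        return idx[0] if idx.size else len(col)

    assert first_zero_crossing(K[:, 1]) > first_zero_crossing(K[:, 0])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def test_simulate_no_modulation_no_background():
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    tr = deer.simulate_trace(P, T_GRID, lam=0.0, k=0.0)
    np.testing.assert_allclose(tr.v, 1.0, atol=1e-9)


def test_simulate_delta_equals_kernel_column():
    r0 = 40.0
    p = np.zeros_like(R_GRID)
    p[np.flatnonzero(R_GRID == r0)[0]] = 1.0
    P = DistanceDistribution(R_GRID, p).normalized()
    tr = deer.simulate_trace(P, T_GRID, lam=1.0, k=0.0)
    col = deer.dipolar_kernel(T_GRID, np.array([r0]))[:, 0]
    np.testing.assert_allclose(tr.v, col, atol=1e-6)


def test_simulate_validates_parameters():
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    with pytest.raises(ValueError):
        deer.simulate_trace(P, T_GRID, lam=1.5)
    with pytest.raises(ValueError):
        deer.simulate_trace(P, T_GRID, k=-0.1)
    with pytest.raises(ValueError):
        deer.simulate_trace(P, T_GRID, noise_sd=0.01, seed=None)


def test_simulation_deterministic_for_seed():
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    a = deer.simulate_trace(P, T_GRID, noise_sd=0.01, seed=5)
    b = deer.simulate_trace(P, T_GRID, noise_sd=0.01, seed=5)
    np.testing.assert_array_equal(a.v, b.v)


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def test_background_flat_case():
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    tr = deer.simulate_trace(P, T_GRID, lam=0.3, k=0.0)
    _, k, lam = deer.correct_background(tr)
    assert abs(k) < 1e-3
    assert abs(lam - 0.3) < 1e-3


def test_background_round_trip_recovery():
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    tr = deer.simulate_trace(P, T_GRID, lam=0.3, k=0.08)
    f, k, lam = deer.correct_background(tr)
    assert abs(k - 0.08) < 0.005
    assert abs(lam - 0.30) < 0.01
    F_true = deer.dipolar_kernel(T_GRID, R_GRID) @ (P.p * np.gradient(R_GRID))
    assert np.max(np.abs(f.v - F_true)) < 0.01


def test_background_flags_absent_modulation():
    tr = deer.DeerTrace(T_GRID, np.exp(-0.05 * T_GRID))
    with pytest.raises(deer.NoDipolarSignalError):
        deer.correct_background(tr)


# ---------------------------------------------------------------------------
# zero time
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def shifted_traces():
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    grid = -0.4 + 0.016 * np.arange(540)
    v0 = deer.simulate_trace(P, grid, lam=0.4, k=0.05).v
    v_shift = deer.simulate_trace(P, grid - 0.08, lam=0.4, k=0.05).v
    return grid, v0, v_shift


def test_zero_time_unshifted(shifted_traces):
    grid, v0, _ = shifted_traces
    t0 = deer.optimize_zero_time(deer.DeerTrace(grid, v0))
    assert abs(t0) <= 0.008  # half a sample step


def test_zero_time_planted_shift(shifted_traces):
    grid, _, v_shift = shifted_traces
    t0 = deer.optimize_zero_time(deer.DeerTrace(grid, v_shift))
    assert abs(t0 - 0.08) <= 0.008


def test_zero_time_noise_stability(shifted_traces):
    grid, _, v_shift = shifted_traces
    rng = np.random.default_rng(0)
    for _ in range(20):
        noisy = deer.DeerTrace(grid, v_shift + rng.normal(0.0, 0.005, grid.size))
        assert abs(deer.optimize_zero_time(noisy) - 0.08) <= 0.016  # one step


def test_zero_time_window_validation(shifted_traces):
    grid, v0, _ = shifted_traces
    with pytest.raises(ValueError):
        deer.optimize_zero_time(deer.DeerTrace(grid, v0), search_window=(-10.0, 20.0))


# ---------------------------------------------------------------------------
# Tikhonov inversion
# ---------------------------------------------------------------------------

def test_delta_recovery_on_coarse_grid():
    r = np.linspace(20.0, 60.0, 30)
    t = deer.default_time_grid(4.0, 0.02)
    p = np.zeros(30)
    p[12] = 1.0
    P = DistanceDistribution(r, p).normalized()
    F = deer.dipolar_kernel(t, r) @ (P.p * np.gradient(r))
    rec = deer.invert_tikhonov(deer.DeerTrace(t, F), r, alpha=0.01)
    assert abs(rec.modal_distance - r[12]) <= np.diff(r)[0]


def test_inversion_matches_bounded_lsq_oracle():
    # independent brute-force constrained least squares on the augmented
    # system (scipy lsq_linear/BVLS) against the production NNLS path
    from scipy.optimize import lsq_linear

    r = np.linspace(20.0, 60.0, 30)
    t = deer.default_time_grid(4.0, 0.02)
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, r)
    K = deer.dipolar_kernel(t, r) * np.gradient(r)
    F = K @ P.p
    L = deer._second_difference(r.size)
    for alpha in (0.1, 1.0, 10.0):
        P_nnls, _, _ = deer._tikhonov_raw(K, F, L, alpha)
        A = np.vstack([K, alpha * L])
        b = np.concatenate([F, np.zeros(L.shape[0])])
        oracle = lsq_linear(A, b, bounds=(0.0, np.inf), method="bvls", tol=1e-14)
        assert np.max(np.abs(P_nnls - oracle.x)) < 1e-4


def test_width_monotone_in_alpha():
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    f = _form_trace(P, noise_sd=0.003, seed=2)
    w_small = deer.invert_tikhonov(f, R_GRID, 1.0).width_at_half_height
    w_large = deer.invert_tikhonov(f, R_GRID, 100.0).width_at_half_height
    assert w_large >= w_small - 1e-6


def test_inversion_rejects_pathological_input():
    zeros = deer.DeerTrace(T_GRID, np.zeros_like(T_GRID))
    with pytest.raises(deer.NoDipolarSignalError):
        deer.invert_tikhonov(zeros, R_GRID, 1.0)
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    with pytest.raises(ValueError):
        deer.invert_tikhonov(_form_trace(P), R_GRID, alpha=-1.0)


# ---------------------------------------------------------------------------
# L-curve
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def bimodal_form_factor():
    P = make_distribution(
        "bimodal", {"means": (40.0, 55.0), "fwhms": (5.0, 5.0)}, R_GRID
    )
    F = deer.dipolar_kernel(T_GRID, R_GRID) @ (P.p * np.gradient(R_GRID))
    rng = np.random.default_rng(4)
    return deer.DeerTrace(T_GRID, F + rng.normal(0.0, 0.01, T_GRID.size))


def test_l_curve_monotone_trade_off(bimodal_form_factor):
    lc = deer.l_curve(bimodal_form_factor, R_GRID)
    assert np.all(np.diff(lc.log_rho) >= -1e-6)  # residual non-decreasing
    assert np.all(np.diff(lc.log_eta) <= 1e-6)  # roughness non-increasing


def test_corner_alpha_resolves_two_peaks(bimodal_form_factor):
    lc = deer.l_curve(bimodal_form_factor, R_GRID)
    P_corner = deer.invert_tikhonov(bimodal_form_factor, R_GRID, lc.alpha)
    P_over = deer.invert_tikhonov(bimodal_form_factor, R_GRID, 100.0 * lc.alpha)
    n_corner = len(find_peaks(P_corner.p, height=0.25 * P_corner.p.max())[0])
    n_over = len(find_peaks(P_over.p, height=0.25 * P_over.p.max())[0])
    assert n_corner == 2
    assert n_over == 1


def test_corner_stable_across_noise_seeds():
    P = make_distribution(
        "bimodal", {"means": (40.0, 55.0), "fwhms": (5.0, 5.0)}, R_GRID
    )
    F = deer.dipolar_kernel(T_GRID, R_GRID) @ (P.p * np.gradient(R_GRID))
    corners = []
    for s in range(10):
        noisy = F + np.random.default_rng(100 + s).normal(0.0, 0.01, T_GRID.size)
        corners.append(deer.l_curve(deer.DeerTrace(T_GRID, noisy), R_GRID).corner_index)
    assert max(corners) - min(corners) <= 1


def test_l_curve_rejects_degenerate_ladder(bimodal_form_factor):
    with pytest.raises(ValueError):
        deer.l_curve(bimodal_form_factor, R_GRID, alphas=np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# spectrum & pipeline
# ---------------------------------------------------------------------------

def test_pake_requires_enough_points():
    with pytest.raises(ValueError):
        deer.pake_spectrum(deer.DeerTrace(T_GRID[:8], np.ones(8)))


def test_broader_distribution_broader_spectrum():
    def spectral_variance(P):
        freq, spec = deer.pake_spectrum(_form_trace(P))
        spec = np.abs(spec)
        sel = (freq > 0.1) & (freq < 10.0)
        w = spec[sel] / spec[sel].sum()
        mu = np.sum(freq[sel] * w)
        return np.sum((freq[sel] - mu) ** 2 * w)

    v_narrow = spectral_variance(
        make_distribution("gaussian", {"mean": 40.0, "fwhm": 3.0}, R_GRID)
    )
    v_broad = spectral_variance(
        make_distribution("gaussian", {"mean": 40.0, "fwhm": 10.0}, R_GRID)
    )
    assert v_broad > v_narrow


def test_full_round_trip_gaussian():
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    tr = deer.simulate_trace(P, T_GRID, lam=0.3, k=0.05, noise_sd=0.005, seed=8)
    res = deer.analyze_trace(tr, R_GRID)
    assert abs(res["P"].modal_distance - 40.0) <= 1.0
    assert abs(res["k"] - 0.05) < 0.005
    assert abs(res["lam"] - 0.3) < 0.02


def test_trace_io_round_trip(tmp_path):
    P = make_distribution("gaussian", {"mean": 40.0, "fwhm": 6.0}, R_GRID)
    tr = deer.simulate_trace(P, T_GRID, lam=0.3, k=0.05, noise_sd=0.005, seed=8)
    p = tmp_path / "trace.dat"
    deer.write_trace(tr, p)
    back = deer.read_trace(p)
    np.testing.assert_allclose(back.t, tr.t, atol=1e-12)
    np.testing.assert_allclose(back.v, tr.v, rtol=1e-6)
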