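"""Four-pulse PELDOR/DEER dipolar evolution: simulation and inversion.

The measured echo trace factorizes as

    V(t) = B(t) * [1 - lam + lam * F(t)],      B(t) = exp(-k*t)

with ``lam`` the modulation depth, ``B`` the homogeneous-3D intermolecular
background and ``F`` the intramolecular form factor

    F(t) = integral K(t, r) P(r) dr,
    K(t, r) = integral_0^1 cos[(1 - 3 z^2) * w(r) * t] dz,
    w(r) = 2 pi D / r^3.

``D`` is the nitroxide point-dipole coupling constant computed from physical
constants (~52.04 MHz nm^3).  Times are in microseconds, distances in
angstroms at the API surface (converted to nm only inside the r^3 law).

Recovering P(r) from F(t) is a Fredholm problem of the first kind, solved by
non-negative Tikhonov regularization with a second-difference roughness
penalty; the regularization factor alpha is chosen at the corner of the
L-curve (log residual norm vs log roughness norm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants as _const
from scipy.optimize import curve_fit, nnls

from .labeling import DistanceDistribution

__all__ = [
    "DIPOLAR_CONSTANT_MHZ_NM3",
    "DeerTrace",
    "NoDipolarSignalError",
    "dipolar_kernel",
    "simulate_trace",
    "correct_background",
    "optimize_zero_time",
    "invert_tikhonov",
    "l_curve",
    "pake_spectrum",
    "analyze_trace",
    "default_time_grid",
]

# mu0/(4 pi) * (g mu_B)^2 / h, expressed in MHz nm^3
_g = abs(_const.value("electron g factor"))
DIPOLAR_CONSTANT_MHZ_NM3 = (
    _const.mu_0 / (4 * np.pi) * (_g * _const.value("Bohr magneton")) ** 2 / _const.h
) * 1e27 / 1e6  # ~52.04

_GL_NODES = 512


class NoDipolarSignalError(ValueError):
    """Raised when a trace carries no usable dipolar modulation."""


@dataclass
class DeerTrace:
    """Dipolar evolution time series (t in microseconds, V dimensionless)."""

    t: np.ndarray
    v: np.ndarray
    lam: float | None = None  # modulation depth
    k: float | None = None  # background rate, 1/us
    t0: float | None = None  # zero time, us

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.v)):
            raise ValueError("intensity contains non-finite values")

    def __len__(self) -> int:
        return self.t.size


def default_time_grid(t_max: float = 8.0, dt: float = 0.016) -> np.ndarray:
    """Uniform time grid 0..t_max microseconds."""
    n = int(round(t_max / dt))
    return dt * np.arange(n + 1)


def _omega_rad_per_us(r_angstrom: np.ndarray) -> np.ndarray:
    """Dipolar angular frequency (rad/us) for distances in angstroms."""
    r_nm = np.asarray(r_angstrom, dtype=float) / 10.0
    if np.any(r_nm <= 0):
        raise ValueError("distances must be positive")
    return 2.0 * np.pi * DIPOLAR_CONSTANT_MHZ_NM3 / r_nm**3


def dipolar_kernel(t_grid: np.ndarray, r_grid: np.ndarray) -> np.ndarray:
    """Powder-averaged dipolar kernel K(t, r).

    Rows follow ``t_grid`` (us), columns ``r_grid`` (A).  The orientation
    average over z = cos(theta) uses Gauss-Legendre quadrature with 512 nodes;
    K(0, r) = 1 and |K| <= 1.  The kernel is even in t, so negative times are
    admitted via |t|.
    """
    t = np.abs(np.asarray(t_grid, dtype=float))
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r_grid))):
        raise ValueError("non-finite grids")
    w = _omega_rad_per_us(r_grid)
    z, gw = np.polynomial.legendre.leggauss(_GL_NODES)
    z = 0.5 * (z + 1.0)  # map [-1,1] -> [0,1]
    gw = 0.5 * gw
    # phase: (1 - 3 z^2) * w(r) * t ; accumulate over quadrature nodes in
    # chunks to bound memory for long grids
    K = np.zeros((t.size, w.size))
    wt = np.outer(t, w)  # (nt, nr)
    for i in range(0, z.size, 64):
        zz = z[i : i + 64]
        gg = gw[i : i + 64]
        K += np.einsum(
            "k,trk->tr", gg, np.cos(wt[:, :, None] * (1.0 - 3.0 * zz**2))
        )
    return K


def _form_factor(P: DistanceDistribution, t_grid: np.ndarray) -> np.ndarray:
    K = dipolar_kernel(t_grid, P.r)
    w = np.gradient(P.r)  # trapezoid weights on a uniform grid
    return K @ (P.p * w)


def simulate_trace(
    P: DistanceDistribution,
    t_grid: np.ndarray | None = None,
    lam: float = 0.3,
    k: float = 0.05,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DeerTrace:
    """Simulate V(t) = exp(-k t) [1 - lam + lam F(t)] + white noise.

    ``lam`` in [0, 1]; ``k`` >= 0 in 1/us.  Deterministic for a fixed seed.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("modulation depth must lie in [0, 1]")
    if k < 0:
        raise ValueError("background rate must be non-negative")
    t = default_time_grid() if t_grid is None else np.asarray(t_grid, dtype=float)
    F = _form_factor(P.normalized(), t)
    v = np.exp(-k * np.abs(t)) * (1.0 - lam + lam * F)
    if noise_sd > 0:
        if seed is None:
            raise ValueError("noisy simulation requires a seed")
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return DeerTrace(t, v, lam=lam, k=k, t0=0.0)


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def correct_background(
    trace: DeerTrace, fit_start_fraction: float = 0.5
) -> tuple[DeerTrace, float, float]:
    """Divide out the homogeneous-3D background and isolate F(t).

    Fits ``a * exp(-k t)`` to the tail (t >= fit_start_fraction * t_max),
    where the form factor has decayed and V ~ (1 - lam) exp(-k t).  Returns
    the form-factor trace (F(0) = 1), the background rate ``k`` and the
    modulation depth ``lam = 1 - a``.
    """
    if not 0.0 < fit_start_fraction < 1.0:
        raise ValueError("fit_start_fraction must lie in (0, 1)")
    t, v = trace.t, trace.v
    pos = t >= 0
    t, v = t[pos], v[pos]
    tail = t >= fit_start_fraction * t[-1]
    if tail.sum() < 4:
        raise ValueError("trace shorter than the background fit window")
    if np.any(v[tail] <= 0):
        raise ValueError("non-positive tail values; cannot fit log background")
    # log-linear start, then nonlinear polish
    slope, intercept = np.polyfit(t[tail], np.log(v[tail]), 1)
    try:
        popt, _ = curve_fit(
            lambda tt, a, kk: a * np.exp(-kk * tt),
            t[tail],
            v[tail],
            p0=[np.exp(intercept), max(-slope, 0.0)],
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise ValueError(f"background fit diverged: {exc}") from exc
    a, k = float(popt[0]), float(popt[1])
    a = min(a, 1.0 - 1e-9)
    lam = 1.0 - a
    if lam <= 1e-3:
        raise NoDipolarSignalError(
            "no dipolar modulation detected (modulation depth ~ 0)"
        )
    reduced = v / (np.exp(-k * t))  # = 1 - lam + lam F
    F = (reduced - (1.0 - lam)) / lam
    return DeerTrace(t, F, lam=lam, k=k, t0=trace.t0), k, lam


def _background_refine(
    trace: DeerTrace,
    K: np.ndarray,
    L: np.ndarray,
    alpha: float,
    k0: float,
    lam0: float,
) -> tuple[float, float]:
    """Joint background/distribution re-fit (separable nonlinear LSQ).

    The nonlinear background parameters (k, lam) are optimized in an outer
    Nelder-Mead loop; at each trial the distribution is the inner regularized
    non-negative solution.  This removes the tail-fit bias that arises when
    the dipolar oscillation has not decayed inside the acquisition window.
    """
    from scipy.optimize import minimize

    t = trace.t[trace.t >= 0]
    v = trace.v[trace.t >= 0]

    def objective(x):
        k, lam = x
        if not (0.0 <= k <= 2.0 and 1e-3 <= lam <= 0.99):
            return 1e6
        F = (v / np.exp(-k * t) - (1.0 - lam)) / lam
        P, _, _ = _tikhonov_raw(K, F, L, alpha)
        model = np.exp(-k * t) * (1.0 - lam + lam * (K @ P))
        return float(np.sum((v - model) ** 2))

    res = minimize(
        objective,
        x0=[k0, lam0],
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 200},
    )
    k, lam = res.x
    return float(k), float(lam)


# ---------------------------------------------------------------------------
# zero time
# ---------------------------------------------------------------------------

def optimize_zero_time(
    trace: DeerTrace, search_window: tuple[float, float] | None = None
) -> float:
    """Locate the dipolar zero time by symmetry of V around its origin.

    The dipolar signal is even in t - t0; the returned origin minimizes the
    mean squared difference between the trace and its mirror image
    (equivalently, minimizes the imaginary part of the Fourier transform).
    Grid search over samples in the window, then parabolic refinement.
    """
    t, v = trace.t, trace.v
    if search_window is None:
        lo, hi = t[0], t[0] + 0.25 * (t[-1] - t[0])
    else:
        lo, hi = search_window
    if lo < t[0] or hi > t[-1] or lo >= hi:
        raise ValueError("search window outside trace")
    cand = np.flatnonzero((t >= lo) & (t <= hi))
    if cand.size == 0:
        raise ValueError("search window contains no samples")
    dt = np.median(np.diff(t))

    def score(tc: float) -> float:
        tau_max = min(tc - t[0], 0.3 * (t[-1] - tc))
        if tau_max <= dt:
            return np.inf
        tau = np.arange(dt, tau_max, dt)
        vp = np.interp(tc + tau, t, v)
        vm = np.interp(tc - tau, t, v)
        return float(np.mean((vp - vm) ** 2))

    scores = np.array([score(t[i]) for i in cand])
    best = int(np.argmin(scores))
    t_best = t[cand[best]]
    # parabolic refinement on the three points around the minimum
    if 0 < best < len(cand) - 1 and np.all(np.isfinite(scores[best - 1 : best + 2])):
        s_m, s_0, s_p = scores[best - 1 : best + 2]
        denom = s_m - 2 * s_0 + s_p
        if denom > 0:
            shift = 0.5 * (s_m - s_p) / denom
            t_best = t_best + np.clip(shift, -1.0, 1.0) * dt
    return float(t_best)


# ---------------------------------------------------------------------------
# Tikhonov inversion
# ---------------------------------------------------------------------------

def _second_difference(n: int) -> np.ndarray:
    L = np.zeros((n - 2, n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


def _tikhonov_raw(K: np.ndarray, F: np.ndarray, L: np.ndarray, alpha: float):
    """Non-negative Tikhonov solution of the augmented system."""
    A = np.vstack([K, alpha * L])
    b = np.concatenate([F, np.zeros(L.shape[0])])
    P, _ = nnls(A, b)
    rho = float(np.linalg.norm(K @ P - F))
    eta = float(np.linalg.norm(L @ P))
    return P, rho, eta


def invert_tikhonov(
    f: DeerTrace, r_grid: np.ndarray, alpha: float
) -> DistanceDistribution:
    """Non-negative Tikhonov inversion of a background-corrected trace.

    Minimizes ``|K P - F|^2 + alpha^2 |L P|^2`` subject to P >= 0, with L the
    second-difference operator; the result is normalized on ``r_grid``.
    """
    if alpha <= 0:
        raise ValueError("regularization factor must be positive")
    F = f.v
    if np.max(np.abs(F)) < 1e-10:
        raise NoDipolarSignalError("form factor is identically zero")
    r = np.asarray(r_grid, dtype=float)
    K = dipolar_kernel(f.t, r) * np.gradient(r)
    L = _second_difference(r.size)
    P, _, _ = _tikhonov_raw(K, F, L, alpha)
    if not np.any(P > 0):
        raise NoDipolarSignalError("inversion produced an empty distribution")
    return DistanceDistribution(r, P).normalized()


@dataclass
class LCurve:
    """L-curve across a regularization ladder with its corner selection."""

    alphas: np.ndarray
    log_rho: np.ndarray  # log residual norm
    log_eta: np.ndarray  # log roughness norm
    curvature: np.ndarray
    corner_index: int

    @property
    def alpha(self) -> float:
        return float(self.alphas[self.corner_index])


def l_curve(
    f: DeerTrace, r_grid: np.ndarray, alphas: np.ndarray | None = None
) -> LCurve:
    """Compute the L-curve over an alpha ladder and pick its corner.

    The corner is the point of maximum curvature of the smoothed
    (log residual, log roughness) curve; ties break toward larger alpha
    (the smoother distribution).
    """
    if alphas is None:
        alphas = np.logspace(-2, 3, 16)
    alphas = np.sort(np.asarray(alphas, dtype=float))
    if alphas.size < 5 or alphas[-1] / alphas[0] < 1e3:
        raise ValueError("alpha ladder must have >= 5 values spanning >= 3 decades")
    r = np.asarray(r_grid, dtype=float)
    K = dipolar_kernel(f.t, r) * np.gradient(r)
    L = _second_difference(r.size)
    rho = np.empty(alphas.size)
    eta = np.empty(alphas.size)
    for i, a in enumerate(alphas):
        _, rho[i], eta[i] = _tikhonov_raw(K, f.v, L, a)
    log_rho = np.log(np.maximum(rho, 1e-300))
    log_eta = np.log(np.maximum(eta, 1e-300))
    # light smoothing before differentiating
    def smooth(y):
        ys = y.copy()
        ys[1:-1] = 0.25 * y[:-2] + 0.5 * y[1:-1] + 0.25 * y[2:]
        return ys

    x, y = smooth(log_rho), smooth(log_eta)
    s = np.log(alphas)
    dx, dy = np.gradient(x, s), np.gradient(y, s)
    ddx, ddy = np.gradient(dx, s), np.gradient(dy, s)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.where(denom > 1e-12, (dx * ddy - dy * ddx) / denom, -np.inf)
    curv[~np.isfinite(curv)] = -np.inf
    # maximum curvature over interior rungs (the one-sided difference at the
    # ladder ends is unreliable); ties toward larger alpha
    interior = curv.copy()
    interior[0] = interior[-1] = -np.inf
    corner = int(alphas.size - 1 - np.argmax(interior[::-1]))
    return LCurve(alphas, log_rho, log_eta, curv, corner)


# ---------------------------------------------------------------------------
# Pake spectrum
# ---------------------------------------------------------------------------

def pake_spectrum(f: DeerTrace) -> tuple[np.ndarray, np.ndarray]:
    """Apodized real Fourier transform of the form factor.

    Returns (frequency in MHz, amplitude).  The trace is symmetrized in t
    (the dipolar signal is even), Hamming-apodized and zero-filled; for a
    single distance r the turning points sit at +-D/r^3.
    """
    if len(f) < 16:
        raise ValueError("too few points for a spectrum (< 16)")
    t, v = f.t, f.v
    dt = np.median(np.diff(t))
    # symmetric extension about t=0
    v_sym = np.concatenate([v[:0:-1], v])
    w = np.hamming(v_sym.size)
    n_fft = int(2 ** np.ceil(np.log2(4 * v_sym.size)))
    spec = np.fft.rfft(v_sym * w, n=n_fft)
    freq = np.fft.rfftfreq(n_fft, d=dt)  # us -> MHz
    # undo the linear phase from the symmetric start at -t_max
    phase = np.exp(2j * np.pi * freq * (v.size - 1) * dt)
    return freq, np.real(spec * phase)


# ---------------------------------------------------------------------------
# full analysis pipeline
# ---------------------------------------------------------------------------

def analyze_trace(
    trace: DeerTrace,
    r_grid: np.ndarray,
    alphas: np.ndarray | None = None,
    fit_start_fraction: float = 0.5,
    refine_background: bool = True,
) -> dict:
    """Background-correct, pick alpha on the L-curve, and invert to P(r).

    When ``refine_background`` is set, the background parameters are re-fit
    once over the full trace using the first-pass form-factor model (this
    removes the tail-fit bias for long distances whose oscillation has not
    decayed inside the acquisition window).
    """
    f, k, lam = correct_background(trace, fit_start_fraction)
    lc = l_curve(f, r_grid, alphas)
    P = invert_tikhonov(f, r_grid, lc.alpha)
    if refine_background:
        r = np.asarray(r_grid, dtype=float)
        K = dipolar_kernel(f.t, r) * np.gradient(r)
        L = _second_difference(r.size)
        k, lam = _background_refine(trace, K, L, lc.alpha, k, lam)
        reduced = trace.v[trace.t >= 0] / np.exp(-k * f.t)
        F = (reduced - (1.0 - lam)) / lam
        f = DeerTrace(f.t, F, lam=lam, k=k, t0=trace.t0)
        lc = l_curve(f, r_grid, alphas)
        P = invert_tikhonov(f, r_grid, lc.alpha)
    return {"form_factor": f, "k": k, "lam": lam, "l_curve": lc, "P": P}


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_trace(trace: DeerTrace, path) -> None:
    np.savetxt(path, np.column_stack([trace.t, trace.v]), header="t_us  V")


def read_trace(path) -> DeerTrace:
    data = np.loadtxt(path)
    return DeerTrace(data[:, 0], data[:, 1])
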