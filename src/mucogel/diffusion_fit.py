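"""Effective-diffusivity estimation from normalized fluorescence profiles.

The working model is one-dimensional Fickian diffusion from a constant
concentration boundary into a semi-infinite medium, whose solution is

    F(x, t) = A * erfc( x / (2 sqrt(D_eff t)) ) + B,

with the amplitude A absorbing normalization error and B an optional
camera background. ``fit_erfc`` fits this closed form jointly over every
(x, t) cell; ``fit_pde`` replaces the closed form with a finite-difference
forward model, which additionally supports a depleting (finite-volume)
reservoir boundary. Uncertainty comes from a bootstrap over frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erfc, erfcinv

from mucogel.diffusion_profiles import ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = ["DiffusionFitResult", "initial_guess", "fit_erfc", "fit_pde", "goodness_of_fit"]

#: erfc(z) = 1/2 at this z; used to invert half-crossing distances.
_Z_HALF = float(erfcinv(0.5))

_FALLBACK_D0 = 1e-7  # cm^2/s, typical macromolecule-in-hydrogel scale


@dataclass
class DiffusionFitResult:
    """Fitted effective diffusivity with diagnostics.

    ``d_eff`` is in cm^2/s. ``ci_low``/``ci_high`` is a percentile
    bootstrap interval over frames (NaN when the bootstrap was skipped).
    ``predicted`` holds the fitted model evaluated on the fit grid.
    """

    d_eff: float
    amplitude: float
    offset: float
    residual_rmse: float
    r_squared: float
    ci_low: float
    ci_high: float
    converged: bool
    model: str
    n_bootstrap: int = 0
    bootstrap_seed: int | None = None
    excluded_frames: list = field(default_factory=list)
    predicted: np.ndarray | None = field(default=None, repr=False)


def _half_crossing_d0(f: np.ndarray, x: np.ndarray, t: np.ndarray) -> float:
    estimates = []
    for j, t_j in enumerate(t):
        col = f[:, j]
        half = 0.5 * col[0]
        below = np.flatnonzero(col < half)
        if below.size == 0 or below[0] == 0 or t_j <= 0:
            continue
        i = below[0]
        # linear interpolation of the crossing tames grid quantization
        frac = (col[i - 1] - half) / (col[i - 1] - col[i]) if col[i - 1] != col[i] else 0.0
        x_half = x[i - 1] + frac * (x[i] - x[i - 1])
        estimates.append((x_half / (2.0 * _Z_HALF)) ** 2 / t_j)
    if not estimates:
        logger.warning("no half-crossing found; falling back to d0 = %.1e cm^2/s", _FALLBACK_D0)
        return _FALLBACK_D0
    return float(np.median(estimates))


def initial_guess(matrix: ProfileMatrix) -> float:
    """Starting diffusivity from per-frame half-crossing distances.

    For each frame, the first axial position where F drops below half its
    interface value gives x_half; inverting erfc(z) = 1/2 yields
    d = (x_half / (2 z_half))^2 / t. The median over frames is returned;
    with no crossing anywhere (flat profiles) a fallback of 1e-7 cm^2/s is
    returned with a logged warning.
    """
    return _half_crossing_d0(matrix.f, matrix.x_grid, matrix.t_grid)


def _erfc_model(x: np.ndarray, t: np.ndarray, d: float, a: float, b: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        z = x[:, None] / (2.0 * np.sqrt(d * t[None, :]))
    return a * erfc(z) + b


def _pack_bounds(fit_amplitude: bool, fit_offset: bool):
    lo, hi = [-14.0], [2.0]  # log10(d) bounds, loose enough for any unit system
    if fit_amplitude:
        lo.append(1e-6)
        hi.append(2.0)
    if fit_offset:
        lo.append(-0.5)
        hi.append(0.5)
    return np.array(lo), np.array(hi)


def _unpack(params: np.ndarray, fit_amplitude: bool, fit_offset: bool) -> tuple[float, float, float]:
    d = 10.0 ** params[0]
    i = 1
    a = params[i] if fit_amplitude else 1.0
    i += fit_amplitude
    b = params[i] if fit_offset else 0.0
    return float(d), float(a), float(b)


def _guard_reference(matrix: ProfileMatrix, tolerance: float) -> np.ndarray:
    """Indices of frames whose reference stays within tolerance of frame 0."""
    if matrix.reference_intensity is None:
        return np.arange(matrix.t_grid.size)
    ref = matrix.reference_intensity
    ok = np.abs(ref - ref[0]) <= tolerance * ref[0]
    if not ok.all():
        logger.warning(
            "excluding %d frame(s) whose reference deviates > %.0f%% from frame 0 "
            "(bleaching/evaporation guard)",
            int((~ok).sum()),
            100 * tolerance,
        )
    return np.flatnonzero(ok)


def _fit_generic(
    matrix: ProfileMatrix,
    forward,
    model_name: str,
    fit_amplitude: bool,
    fit_offset: bool,
    frame_weights: np.ndarray | None,
    n_bootstrap: int,
    seed: int,
    n_restarts: int,
    reference_guard: float,
) -> DiffusionFitResult:
    if np.any(matrix.t_grid <= 0):
        raise ValueError("all frame times must be > 0 (the model is singular at t = 0)")
    if not np.all(np.isfinite(matrix.f)):
        raise ValueError("profile matrix contains non-finite values")

    keep = _guard_reference(matrix, reference_guard)
    excluded = sorted(set(range(matrix.t_grid.size)) - set(keep.tolist()))
    f = matrix.f[:, keep]
    t = matrix.t_grid[keep]
    x = matrix.x_grid
    if f.shape[1] < 1:
        raise ValueError("no frames left after the reference guard")

    weights = np.ones(t.size) if frame_weights is None else np.asarray(frame_weights, float)[keep]

    degenerate = float(np.std(f)) < 1e-12

    lo, hi = _pack_bounds(fit_amplitude, fit_offset)

    def solve(f_sub: np.ndarray, t_sub: np.ndarray, w_sub: np.ndarray, rng: np.random.Generator):
        d0 = _half_crossing_d0(f_sub, x, t_sub)
        best = None
        for attempt in range(n_restarts + 1):
            log_d0 = np.clip(np.log10(d0) + (0 if attempt == 0 else rng.normal(0, 0.5)), lo[0], hi[0])
            p0 = [log_d0]
            if fit_amplitude:
                p0.append(np.clip(f_sub[0].mean(), 0.05, 2.0))
            if fit_offset:
                p0.append(0.0)

            def residuals(p):
                d, a, b = _unpack(p, fit_amplitude, fit_offset)
                return ((forward(x, t_sub, d) * a + b - f_sub) * w_sub[None, :]).ravel()

            sol = least_squares(
                residuals, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-10
            )
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.cost < 1e-20:
                break
        return best

    rng = np.random.default_rng(seed)
    sol = solve(f, t, weights, rng)
    d, a, b = _unpack(sol.x, fit_amplitude, fit_offset)
    predicted = forward(x, t, d) * a + b
    resid = f - predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    converged = bool(sol.success) and not degenerate

    ci_low = ci_high = float("nan")
    if n_bootstrap > 0 and converged and t.size >= 2:
        boots = []
        for _ in range(n_bootstrap):
            idx = np.sort(rng.integers(0, t.size, t.size))
            bsol = solve(f[:, idx], t[idx], weights[idx], rng)
            boots.append(_unpack(bsol.x, fit_amplitude, fit_offset)[0])
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        ci_low = min(float(ci_low), d)
        ci_high = max(float(ci_high), d)

    return DiffusionFitResult(
        d_eff=d,
        amplitude=a,
        offset=b,
        residual_rmse=rmse,
        r_squared=max(0.0, min(1.0, r2)),
        ci_low=ci_low,
        ci_high=ci_high,
        converged=converged,
        model=model_name,
        n_bootstrap=n_bootstrap,
        bootstrap_seed=seed,
        excluded_frames=excluded,
        predicted=predicted,
    )


def fit_erfc(
    matrix: ProfileMatrix,
    fit_amplitude: bool = True,
    fit_offset: bool = False,
    frame_weights: np.ndarray | None = None,
    n_bootstrap: int = 200,
    seed: int = 0,
    n_restarts: int = 5,
    reference_guard: float = 0.2,
) -> DiffusionFitResult:
    """Fit F = A erfc(x / (2 sqrt(D t))) + B jointly over all cells.

    A is free in (0, 2] by default (normalization slack); B defaults to a
    fixed 0 and is opt-in. Uses bounded trust-region least squares on
    log10(D) with restarts from jittered half-crossing initial guesses.
    The confidence interval is a percentile bootstrap resampling frames
    with replacement (frames, not pixels, because axial pixels within a
    frame are strongly correlated).
    """

    def forward(x, t, d):
        return _erfc_model(x, t, d, 1.0, 0.0)

    return _fit_generic(
        matrix, forward, "erfc", fit_amplitude, fit_offset,
        frame_weights, n_bootstrap, seed, n_restarts, reference_guard,
    )


def _pde_forward_factory(
    x_eval: np.ndarray,
    reservoir_mode: str,
    reservoir_volume_ratio: float,
    min_domain_factor: float,
    max_nodes: int,
    grid_refine: float = 1.0,
):
    """Build a forward model C(x, t; d) from the implicit finite-difference solver.

    The internal grid adapts to the diffusion length for the requested d:
    the domain extends well past both the profile window and the penetration
    depth (so the zero-flux far boundary stays inert), and the spacing
    resolves the earliest-frame front. The solution is interpolated onto
    the evaluation grid.
    """
    from mucogel.synthetic_data import _thomas_step

    window = float(x_eval[-1])
    depleting = reservoir_mode == "depleting"

    def forward(x: np.ndarray, t: np.ndarray, d: float) -> np.ndarray:
        t_min, t_max = float(t[0]), float(t[-1])
        length = max(min_domain_factor * window, window + 6.0 * np.sqrt(d * t_max))
        dx = np.sqrt(d * t_min) / (6.0 * grid_refine)
        dx = float(np.clip(dx, length / max_nodes, length / 100))
        n_nodes = int(round(length / dx)) + 1
        grid = np.linspace(0.0, length, n_nodes)
        dx = grid[1] - grid[0]
        res_len = reservoir_volume_ratio * length + 0.5 * dx

        c = np.zeros(n_nodes)
        c[0] = 1.0
        c_res = 1.0
        out = np.empty((x.size, t.size))
        t_prev = 0.0
        steps_taken = 0
        for j, t_j in enumerate(t):
            span = t_j - t_prev
            n_sub = max(2, int(np.ceil(d * span / (4.0 * dx**2))))
            dt = span / n_sub
            r = d * dt / dx**2
            for _ in range(n_sub):
                theta = 1.0 if steps_taken < 2 else 0.5
                boundary = c_res if depleting else 1.0
                if depleting:
                    m_old = np.trapezoid(c, dx=dx) - 0.5 * dx * c[0]
                c = _thomas_step(c, r, theta, boundary)
                if depleting:
                    gained = (np.trapezoid(c, dx=dx) - 0.5 * dx * c[0]) - m_old
                    c_res = max(c_res - gained / res_len, 0.0)
                    c[0] = c_res
                steps_taken += 1
            out[:, j] = np.interp(x, grid, c)
            t_prev = t_j
        return out

    return forward


def fit_pde(
    matrix: ProfileMatrix,
    reservoir_mode: str = "constant",
    reservoir_volume_ratio: float = 10.0,
    fit_amplitude: bool = True,
    fit_offset: bool = False,
    frame_weights: np.ndarray | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
    n_restarts: int = 2,
    reference_guard: float = 0.2,
    domain_factor: float = 1.5,
    max_nodes: int = 2000,
    grid_refine: float = 1.0,
) -> DiffusionFitResult:
    """Fit with a finite-difference forward model instead of the closed form.

    Relaxes the semi-infinite assumption of the erfc model: the simulated
    domain is finite (``domain_factor`` times the profile window) and the
    reservoir may deplete as tracer enters the gel (``reservoir_mode=
    "depleting"`` with the given volume ratio). Under a constant boundary
    and an ample domain this agrees with :func:`fit_erfc`.
    """
    if reservoir_mode not in ("constant", "depleting"):
        raise ValueError(f"unknown reservoir_mode {reservoir_mode!r}")
    forward = _pde_forward_factory(
        matrix.x_grid, reservoir_mode, reservoir_volume_ratio, domain_factor, max_nodes,
        grid_refine,
    )
    return _fit_generic(
        matrix, forward, f"pde_{reservoir_mode}", fit_amplitude, fit_offset,
        frame_weights, n_bootstrap, seed, n_restarts, reference_guard,
    )


def goodness_of_fit(matrix: ProfileMatrix, result: DiffusionFitResult) -> dict:
    """Residual summaries of a fit against the matrix it was fit to.

    Returns r^2, rmse and the residual field (observed minus fitted) for
    plotting. Raises when the result's stored prediction does not match
    the matrix grid (the fit excluded frames, or came from another matrix).
    """
    if result.predicted is None:
        raise ValueError("result carries no stored prediction")
    if result.predicted.shape != matrix.f.shape:
        raise ValueError(
            f"grid mismatch: prediction {result.predicted.shape} vs matrix {matrix.f.shape}"
        )
    resid = matrix.f - result.predicted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((matrix.f - matrix.f.mean()) ** 2))
    return {
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "residual_field": resid,
    }
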