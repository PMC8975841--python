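"""Synthetic inputs with known ground truth for every pipeline stage.

Generates the raw material the analysis modules consume: finite-difference
solutions of one-dimensional Fickian diffusion in a hydrogel channel,
rendered fluorescence image stacks with shot noise and photobleaching,
spherical-cap droplet images at prescribed contact angles, Poisson
spot-plating colony counts, and viscoelastic frequency sweeps from a
single-mode Maxwell model.

All generators are pure functions of their configuration and seed: the same
inputs always produce bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import erfc

from mucogel.assay_metrics import FrequencySweep, SpotCountTable

__all__ = [
    "DiffusionSimConfig",
    "ConcentrationField",
    "NoiseModel",
    "analytic_erfc_solution",
    "simulate_diffusion_pde",
    "render_image_stack",
    "write_stack_tiff",
    "simulate_droplet_image",
    "simulate_spot_counts",
    "simulate_frequency_sweep",
]


@dataclass(frozen=True)
class DiffusionSimConfig:
    """Geometry, transport and acquisition parameters of a diffusion assay.

    The default geometry mirrors a straight 10 mm hydrogel channel imaged
    every 4 minutes, with the tracer reservoir abutting the gel at x = 0.

    Parameters
    ----------
    d_true : float
        Ground-truth diffusivity, cm^2/s.
    domain_length : float
        Channel length, cm.
    dx : float
        Spatial grid spacing, cm.
    frame_interval : float
        Time between stored frames, s.
    n_frames : int
        Number of stored frames, including the t = 0 initial condition.
    reservoir_mode : str
        ``"constant"`` holds the x = 0 boundary at ``c0``;
        ``"depleting"`` models the reservoir as a well-mixed compartment
        whose concentration drops as tracer enters the gel.
    reservoir_volume_ratio : float
        Reservoir volume / channel volume; only used in depleting mode.
    c0 : float
        Initial reservoir concentration, arbitrary fluorescence units.
    seed : int
        Seed recorded alongside the field (the PDE itself is deterministic).
    """

    d_true: float = 5e-7
    domain_length: float = 1.0
    dx: float = 1e-3
    frame_interval: float = 240.0
    n_frames: int = 31
    reservoir_mode: str = "constant"
    reservoir_volume_ratio: float = 10.0
    c0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_true < 0:
            raise ValueError("d_true must be >= 0")
        if self.dx <= 0:
            raise ValueError("dx must be > 0")
        if self.domain_length < 10 * self.dx:
            raise ValueError("domain_length must be >= 10 * dx")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.reservoir_mode not in ("constant", "depleting"):
            raise ValueError(f"unknown reservoir_mode {self.reservoir_mode!r}")
        if self.reservoir_volume_ratio <= 0:
            raise ValueError("reservoir_volume_ratio must be > 0")
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")


@dataclass
class ConcentrationField:
    """Tracer concentration C(x, t) on a space-time grid.

    ``values[i, j]`` is the concentration at ``x_grid[i]`` (cm from the
    reservoir-hydrogel interface) and ``t_grid[j]`` (s from the first
    frame). ``reservoir`` holds the per-frame reservoir concentration in
    depleting mode (None for a constant boundary); ``reservoir_length`` is
    the effective well-mixed reservoir length in cm, including the
    interface half-cell, so that per-step mass bookkeeping closes exactly.
    """

    values: np.ndarray
    x_grid: np.ndarray
    t_grid: np.ndarray
    c0: float
    reservoir: np.ndarray | None = None
    reservoir_length: float | None = None

    def channel_mass(self, frame: int) -> float:
        """Mass per unit cross-section in the gel at a frame (boundary node excluded)."""
        dx = self.x_grid[1] - self.x_grid[0]
        c = self.values[:, frame]
        return float(np.trapezoid(c, dx=dx) - 0.5 * dx * c[0])


@dataclass(frozen=True)
class NoiseModel:
    """Camera/photophysics model for rendering fluorescence frames.

    Shot noise is Poisson with ``poisson_gain`` photons per concentration
    unit; read noise is additive Gaussian; photobleaching multiplies each
    frame by exp(-bleach_rate * t).
    """

    gaussian_sigma: float = 0.02
    poisson_gain: float = 100.0
    bleach_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gaussian_sigma", "poisson_gain", "bleach_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def analytic_erfc_solution(
    x: np.ndarray | float, t: np.ndarray | float, d: float, c0: float = 1.0
) -> np.ndarray | float:
    """Concentration for 1-D diffusion into a semi-infinite medium.

    With a constant-concentration boundary C(0, t) = c0 and C(x, 0) = 0,
    the solution is C(x, t) = c0 * erfc(x / (2 sqrt(d t))).

    Raises
    ------
    ValueError
        If ``t <= 0`` or ``d <= 0`` (the similarity variable is undefined).
    """
    x = np.asarray(x, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("t must be > 0")
    if d <= 0:
        raise ValueError("d must be > 0")
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    return c0 * erfc(x / (2.0 * np.sqrt(d * t_arr)))


def _thomas_step(c: np.ndarray, r: float, theta: float, boundary: float) -> np.ndarray:
    """One theta-scheme step of dC/dt = D d2C/dx2 with Dirichlet left, Neumann right.

    r = D dt / dx^2. theta = 1 is backward Euler, 0.5 is Crank-Nicolson.
    """
    n = c.size
    # explicit part
    rhs = c.copy()
    lap = np.empty(n)
    lap[1:-1] = c[:-2] - 2 * c[1:-1] + c[2:]
    lap[0] = 0.0
    lap[-1] = 2 * (c[-2] - c[-1])  # mirror ghost: zero flux
    rhs += (1 - theta) * r * lap
    rhs[0] = boundary

    # implicit tridiagonal (banded form for solve_banded)
    ab = np.zeros((3, n))
    ab[0, 1:] = -theta * r          # superdiagonal
    ab[1, :] = 1 + 2 * theta * r    # diagonal
    ab[2, :-1] = -theta * r         # subdiagonal
    ab[1, 0] = 1.0
    ab[0, 1] = 0.0
    ab[0, -1] = -2 * theta * r      # Neumann mirror at right edge
    return solve_banded((1, 1), ab, rhs)


def simulate_diffusion_pde(config: DiffusionSimConfig) -> ConcentrationField:
    """Solve dC/dt = D d2C/dx2 on the channel with an implicit scheme.

    The left boundary (x = 0) is the reservoir interface: held at ``c0``
    in constant mode, or at a well-mixed reservoir concentration that
    drops by (mass entering the gel) / (effective reservoir volume) each
    internal step in depleting mode. The right boundary is zero-flux.

    Time stepping is Crank-Nicolson with two backward-Euler startup steps
    to damp the oscillations the initial concentration discontinuity would
    otherwise excite; there is no stability restriction on the step size,
    which is chosen internally for accuracy.
    """
    n_nodes = int(round(config.domain_length / config.dx)) + 1
    x = np.linspace(0.0, config.domain_length, n_nodes)
    t = config.frame_interval * np.arange(config.n_frames)

    c = np.zeros(n_nodes)
    c[0] = config.c0
    values = np.empty((n_nodes, config.n_frames))
    values[:, 0] = c

    if config.d_true == 0.0:
        values[:] = c[:, None]
        reservoir = (
            np.full(config.n_frames, config.c0)
            if config.reservoir_mode == "depleting"
            else None
        )
        res_len = (
            config.reservoir_volume_ratio * config.domain_length + 0.5 * config.dx
            if config.reservoir_mode == "depleting"
            else None
        )
        return ConcentrationField(values, x, t, config.c0, reservoir, res_len)

    # accuracy-driven substep choice: keep the diffusion number moderate
    r_max = 2.0
    n_sub = max(4, int(np.ceil(config.d_true * config.frame_interval / (r_max * config.dx**2))))
    dt = config.frame_interval / n_sub
    r = config.d_true * dt / config.dx**2
    if not np.isfinite(r) or r <= 0:
        raise ValueError("discretization produced a non-finite diffusion number")

    depleting = config.reservoir_mode == "depleting"
    # interface half-cell is counted with the reservoir so mass closes exactly
    res_len = config.reservoir_volume_ratio * config.domain_length + 0.5 * config.dx
    c_res = config.c0
    reservoir = np.full(config.n_frames, config.c0) if depleting else None

    def channel_mass(arr: np.ndarray) -> float:
        return float(np.trapezoid(arr, dx=config.dx) - 0.5 * config.dx * arr[0])

    steps_taken = 0
    for j in range(1, config.n_frames):
        for _ in range(n_sub):
            theta = 1.0 if steps_taken < 2 else 0.5
            boundary = c_res if depleting else config.c0
            m_old = channel_mass(c)
            c_new = _thomas_step(c, r, theta, boundary)
            if not np.all(np.isfinite(c_new)):
                raise FloatingPointError("diffusion solve produced non-finite values")
            if depleting:
                gained = channel_mass(c_new) - m_old
                c_res = max(c_res - gained / res_len, 0.0)
                c_new[0] = c_res
            c = c_new
            steps_taken += 1
        values[:, j] = c
        if depleting:
            reservoir[j] = c_res

    values = np.clip(values, 0.0, None)
    return ConcentrationField(
        values, x, t, config.c0, reservoir, res_len if depleting else None
    )


def render_image_stack(
    field: ConcentrationField,
    noise: NoiseModel,
    pixel_size: float = 1e-3,
    channel_width_px: int = 50,
    reservoir_px: int = 0,
) -> np.ndarray:
    """Render a concentration field into a time-lapse fluorescence stack.

    Each frame samples the concentration at pixel centers (i + 0.5) *
    ``pixel_size`` along the channel axis, replicates that profile across
    ``channel_width_px`` rows, applies exponential photobleaching, Poisson
    shot noise (``poisson_gain`` photons per unit), then additive Gaussian
    read noise. ``reservoir_px`` optional columns of reservoir-level
    intensity are prepended so the gel-liquid interface is visible at a
    known pixel.

    Returns a float array of shape (n_frames, channel_width_px, n_px).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    length = field.x_grid[-1] - field.x_grid[0]
    n_px = int(np.floor(length / pixel_size))
    if n_px < 1:
        raise ValueError("pixel_size larger than the simulated domain")
    if channel_width_px < 1:
        raise ValueError("channel_width_px must be >= 1")

    x_px = (np.arange(n_px) + 0.5) * pixel_size
    rng = np.random.default_rng(noise.seed)
    n_frames = field.t_grid.size
    frames = np.empty((n_frames, channel_width_px, reservoir_px + n_px))

    for j in range(n_frames):
        profile = np.interp(x_px, field.x_grid, field.values[:, j])
        if reservoir_px:
            boundary = (
                field.reservoir[j] if field.reservoir is not None else field.values[0, j]
            )
            profile = np.concatenate([np.full(reservoir_px, boundary), profile])
        frame = np.tile(profile, (channel_width_px, 1))
        frame *= np.exp(-noise.bleach_rate * field.t_grid[j])
        if noise.poisson_gain > 0:
            frame = rng.poisson(np.clip(frame, 0, None) * noise.poisson_gain) / noise.poisson_gain
        if noise.gaussian_sigma > 0:
            frame = frame + rng.normal(0.0, noise.gaussian_sigma, frame.shape)
        frames[j] = frame
    return frames


def write_stack_tiff(
    path: str | Path,
    stack: np.ndarray,
    ground_truth: dict | None = None,
    scale: float | None = None,
) -> float:
    """Write a stack as a multi-page 16-bit TIFF plus a JSON sidecar.

    Intensities are linearly scaled so the stack maximum maps near the top
    of the 16-bit range (or by an explicit ``scale`` in counts per unit).
    The sidecar ``<path>.json`` records the scale and any ground-truth
    metadata (true diffusivity, grid, seed). Returns the scale used.
    """
    import tifffile

    path = Path(path)
    if scale is None:
        peak = float(stack.max())
        scale = 60000.0 / peak if peak > 0 else 1.0
    data = np.clip(stack * scale, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {"scale_counts_per_unit": scale}
    if ground_truth:
        sidecar.update(ground_truth)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return scale


def simulate_droplet_image(
    theta_deg: float,
    base_radius_px: float,
    baseline_row: int,
    image_shape: tuple[int, int] = (400, 400),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a side-view sessile droplet as a circular segment.

    A droplet whose cross-section is a circular segment of contact angle
    ``theta_deg`` rests on a horizontal substrate at ``baseline_row``
    (image rows increase downward; the droplet occupies rows above the
    baseline). Bright droplet (1.0) on dark background (0.0) with a
    ~1-pixel anti-aliased rim, plus optional Gaussian noise.

    Returns ``(image, truth)`` where truth records the contact angle, cap
    circle center/radius, base radius, and baseline row.
    """
    if not 0 < theta_deg < 180:
        raise ValueError("theta_deg must lie in (0, 180)")
    if base_radius_px <= 0:
        raise ValueError("base_radius_px must be > 0")
    h_img, w_img = image_shape
    theta = np.deg2rad(theta_deg)
    radius = base_radius_px / np.sin(theta)
    cx = w_img / 2.0
    cy = baseline_row + radius * np.cos(theta)  # below baseline for theta < 90
    cap_height = base_radius_px * np.tan(theta / 2.0)
    half_width = base_radius_px if theta_deg <= 90 else radius

    if baseline_row - cap_height < 1 or baseline_row >= h_img:
        raise ValueError("droplet cap does not fit vertically in the frame")
    if cx - half_width < 1 or cx + half_width > w_img - 1:
        raise ValueError("droplet cap does not fit horizontally in the frame")

    rows = np.arange(h_img)[:, None]
    cols = np.arange(w_img)[None, :]
    dist = np.hypot(cols - cx, rows - cy)
    inside = np.clip(radius - dist + 0.5, 0.0, 1.0)  # soft 1-px edge
    above = np.clip(baseline_row - rows + 0.5, 0.0, 1.0)
    image = inside * above

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, image.shape)

    truth = {
        "theta_deg": float(theta_deg),
        "base_radius_px": float(base_radius_px),
        "baseline_row": int(baseline_row),
        "circle_center": (float(cx), float(cy)),
        "circle_radius": float(radius),
        "cap_height_px": float(cap_height),
    }
    return image, truth


def simulate_spot_counts(
    true_cfu_per_ml: float,
    spot_volume_ml: float = 0.02,
    dilution_exponents: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9),
    seed: int = 0,
) -> SpotCountTable:
    """Draw Poisson colony counts for a serial-dilution spot-plating assay.

    Each dilution 10^-e receives an independent Poisson count with mean
    ``true_cfu_per_ml * spot_volume_ml * 10**-e``, the sampling model for
    well-mixed suspensions spotted at small volume.
    """
    if true_cfu_per_ml < 0:
        raise ValueError("true_cfu_per_ml must be >= 0")
    if spot_volume_ml <= 0:
        raise ValueError("spot_volume_ml must be > 0")
    rng = np.random.default_rng(seed)
    exps = np.asarray(dilution_exponents, dtype=int)
    means = true_cfu_per_ml * spot_volume_ml * np.power(10.0, -exps.astype(float))
    counts = rng.poisson(means)
    return SpotCountTable(
        dilution_exponent=exps,
        spot_volume_ml=np.full(exps.size, spot_volume_ml),
        count=counts,
    )


def simulate_frequency_sweep(
    modulus_plateau: float,
    relaxation_time: float,
    omega_grid: np.ndarray,
    elastic_plateau: float = 0.0,
) -> FrequencySweep:
    """Single-mode Maxwell frequency sweep with optional elastic plateau.

    G'(w) = Ge + G w^2 tau^2 / (1 + w^2 tau^2)
    G"(w) =      G w   tau   / (1 + w^2 tau^2)

    ``relaxation_time = inf`` gives the Hookean limit G' = Ge + G, G" = 0.
    """
    omega = np.asarray(omega_grid, dtype=float)
    if omega.size == 0 or np.any(omega <= 0) or np.any(np.diff(omega) <= 0):
        raise ValueError("omega_grid must be positive and strictly increasing")
    if modulus_plateau < 0 or elastic_plateau < 0:
        raise ValueError("moduli must be >= 0")
    if relaxation_time <= 0:
        raise ValueError("relaxation_time must be > 0")

    if np.isinf(relaxation_time):
        g_p = np.full(omega.size, elastic_plateau + modulus_plateau)
        g_pp = np.zeros(omega.size)
    else:
        wt = omega * relaxation_time
        g_p = elastic_plateau + modulus_plateau * wt**2 / (1 + wt**2)
        g_pp = modulus_plateau * wt / (1 + wt**2)
    return FrequencySweep(omega=omega, g_prime=g_p, g_double_prime=g_pp)
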