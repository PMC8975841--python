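"""Extract normalized fluorescence profiles F(x, t) from diffusion image stacks.

The diffusion assay images a tracer entering a hydrogel channel from a
liquid reservoir. This module locates the reservoir-gel interface, averages
intensity across the channel width to produce axial profiles over time, and
normalizes them against a reference intensity, yielding the space-time
matrix the diffusion model is fit to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileMatrix",
    "load_stack",
    "detect_interface",
    "extract_profiles",
    "normalize_profiles",
    "select_frames",
]


@dataclass
class ProfileMatrix:
    """Normalized fluorescence F on an (x, t) grid.

    ``f[i, j]`` is the normalized intensity at ``x_grid[i]`` cm from the
    interface and ``t_grid[j]`` seconds of elapsed imaging time.
    """

    f: np.ndarray
    x_grid: np.ndarray
    t_grid: np.ndarray
    interface_px: int | None = None
    reference_intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if not np.all(np.isfinite(self.f)):
            raise ValueError("profile matrix contains non-finite values")
        if self.f.shape != (self.x_grid.size, self.t_grid.size):
            raise ValueError("f must have shape (len(x_grid), len(t_grid))")
        if self.x_grid[0] < 0 or np.any(np.diff(self.x_grid) <= 0):
            raise ValueError("x_grid must be non-negative and strictly increasing")
        if np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing")
        if self.reference_intensity is not None:
            self.reference_intensity = np.asarray(self.reference_intensity, dtype=float)
            if np.any(self.reference_intensity <= 0):
                raise ValueError("reference_intensity must be > 0 for every frame")


def load_stack(path: str | Path) -> np.ndarray:
    """Load an image stack from a multi-page TIFF or a directory of frames.

    Directory frames are sorted lexicographically. Returns a float array of
    shape (n_frames, height, width).
    """
    import tifffile

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        frames = [tifffile.imread(p) if p.suffix.lower() in (".tif", ".tiff") else _read_any(p) for p in files]
        stack = np.stack(frames)
    else:
        stack = tifffile.imread(path)
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a (frames, height, width) stack, got shape {stack.shape}")
    return stack


def _read_any(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def detect_interface(
    first_frame: np.ndarray,
    axis: int = 1,
    smooth_sigma: float = 2.0,
    manual_override: int | None = None,
    min_gradient_snr: float = 5.0,
) -> int:
    """Locate the reservoir-hydrogel interface along the channel axis.

    The frame is averaged across the channel width, smoothed with a
    Gaussian (sigma 2 px, which does not shift a step edge), and the pixel
    of maximum axial gradient magnitude is returned. A ``manual_override``
    always wins. Raises if the strongest gradient is indistinguishable from
    the noise floor (uniform frame).
    """
    if manual_override is not None:
        return int(manual_override)
    frame = np.asarray(first_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a single 2-D frame")
    profile = frame.mean(axis=0 if axis == 1 else 1)
    smoothed = gaussian_filter1d(profile, smooth_sigma)
    grad = np.abs(np.diff(smoothed))
    if grad.size == 0:
        raise ValueError("frame too small for interface detection")
    noise = np.median(grad) + 1e-12
    peak = grad.max()
    if peak < min_gradient_snr * noise or peak < 1e-9 * (abs(smoothed).max() + 1e-30):
        raise ValueError(
            "no interface found: axial gradient is below the noise floor "
            "(supply manual_override if the interface position is known)"
        )
    return int(np.argmax(grad))


def extract_profiles(
    stack: np.ndarray,
    interface_px: int,
    profile_length: float = 0.2,
    pixel_size: float = 1e-3,
    width_band: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average intensity across the channel width into axial profiles.

    For each frame, the mean over rows ``width_band`` (default: central 60%
    of the channel, avoiding wall artifacts) is taken at each axial pixel
    from ``interface_px`` to ``interface_px + profile_length/pixel_size``.

    Returns ``(raw, x_grid)``: the raw intensity matrix of shape
    (n_axial_px, n_frames) and axial positions at pixel centers, in cm from
    the interface.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, height, width) stack")
    n_frames, height, width = stack.shape
    n_px = int(round(profile_length / pixel_size))
    if interface_px < 0 or interface_px + n_px > width:
        max_len = (width - interface_px) * pixel_size
        raise ValueError(
            f"profile window exceeds frame: maximum feasible profile_length is {max_len:.4g} cm"
        )
    if width_band is None:
        lo = int(round(0.2 * height))
        hi = max(lo + 1, int(round(0.8 * height)))
        width_band = (lo, hi)
    lo, hi = width_band
    if not 0 <= lo < hi <= height:
        raise ValueError("width_band out of bounds")

    band = stack[:, lo:hi, interface_px : interface_px + n_px]
    raw = band.mean(axis=1).T  # (n_axial_px, n_frames)
    x_grid = (np.arange(n_px) + 0.5) * pixel_size
    return raw, x_grid


def normalize_profiles(
    raw: np.ndarray,
    reference: np.ndarray | float,
    x_grid: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
    interface_px: int | None = None,
) -> ProfileMatrix:
    """Normalize raw profiles by a per-frame reference intensity.

    ``reference`` is either a scalar or a per-frame vector (e.g. the mean
    intensity of a channel containing only fluorescent solution). Frames
    whose reference is NaN fall back to the first finite reference value,
    with a logged warning.
    """
    raw = np.asarray(raw, dtype=float)
    n_frames = raw.shape[1]
    ref = np.broadcast_to(np.asarray(reference, dtype=float), (n_frames,)).copy()
    missing = ~np.isfinite(ref)
    if missing.any():
        finite = ref[~missing]
        if finite.size == 0:
            raise ValueError("no finite reference intensity available")
        logger.warning(
            "reference missing for %d frame(s); falling back to first finite value",
            int(missing.sum()),
        )
        ref[missing] = finite[0]
    if np.any(ref <= 0):
        raise ValueError("reference intensity must be strictly positive for every frame")

    if x_grid is None:
        x_grid = np.arange(raw.shape[0], dtype=float)
    if t_grid is None:
        t_grid = np.arange(1, n_frames + 1, dtype=float)
    return ProfileMatrix(
        f=raw / ref[None, :],
        x_grid=np.asarray(x_grid, dtype=float),
        t_grid=np.asarray(t_grid, dtype=float),
        interface_px=interface_px,
        reference_intensity=ref,
    )


def select_frames(
    matrix: ProfileMatrix, n_frames: int = 30, skip_initial: int = 0
) -> ProfileMatrix:
    """Keep an analysis window of frames (default: the first 30).

    ``skip_initial`` drops leading frames; elapsed times are retained from
    the acquisition clock, not re-zeroed, so the diffusion model sees the
    true elapsed time of each frame.
    """
    total = matrix.t_grid.size
    if n_frames <= 0:
        raise ValueError("n_frames must be > 0")
    if skip_initial < 0:
        raise ValueError("skip_initial must be >= 0")
    if skip_initial + n_frames > total:
        raise ValueError(
            f"requested frames [{skip_initial}, {skip_initial + n_frames}) "
            f"but only {total} frames are available"
        )
    sl = slice(skip_initial, skip_initial + n_frames)
    return ProfileMatrix(
        f=matrix.f[:, sl].copy(),
        x_grid=matrix.x_grid.copy(),
        t_grid=matrix.t_grid[sl].copy(),
        interface_px=matrix.interface_px,
        reference_intensity=(
            matrix.reference_intensity[sl].copy()
            if matrix.reference_intensity is not None
            else None
        ),
    )
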