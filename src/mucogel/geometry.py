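"""Sessile-droplet contact angles and top-view circularity.

Stability readouts for dextran droplets deposited on hydrogel surfaces
within a PEG-dextran aqueous two-phase system: the contact angle of a
side-view droplet against a horizontal substrate (a proxy for interfacial
tension and droplet containment), and the circularity 4*pi*A/P^2 of a
top-view droplet footprint.

Droplets at these scales are near-spherical, so the default contact-angle
method fits a circle to the droplet surface and takes the tangent at each
contact point; a local polynomial-tangent method is kept for irregular
droplets. Image convention: rows increase downward, the droplet sits above
its baseline row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage import measure
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "ContactAngleResult",
    "CircularityResult",
    "segment_droplet",
    "detect_baseline",
    "measure_contact_angles",
    "circularity",
]


@dataclass
class ContactAngleResult:
    """Left/right/mean interior contact angles (degrees) of a sessile droplet."""

    theta_left: float
    theta_right: float
    theta_mean: float
    baseline_row: float
    contact_points: tuple[tuple[float, float], tuple[float, float]]
    method: str

    def __post_init__(self) -> None:
        for th in (self.theta_left, self.theta_right):
            if not 0 < th < 180:
                raise ValueError("contact angles must lie in (0, 180) degrees")


@dataclass
class CircularityResult:
    """Shape compactness 4*pi*area/perimeter^2 of a single mask component."""

    circularity: float
    area: float
    perimeter: float

    def __post_init__(self) -> None:
        if not 0 < self.circularity <= 1.05:  # discretization tolerance
            raise ValueError("circularity must lie in (0, 1.05]")


def segment_droplet(
    image: np.ndarray,
    threshold_method: str = "otsu",
    threshold: float | None = None,
    invert: bool = False,
    min_area_px: int = 50,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Extract the droplet outline as an ordered sub-pixel contour.

    Thresholds the image (Otsu by default, or a fixed value), keeps the
    largest connected component above ``min_area_px``, and returns its
    outer contour from sub-pixel marching squares, Gaussian-smoothed along
    the contour. Contour points are (row, col) pairs.
    """
    image = np.asarray(image, dtype=float)
    if invert:
        image = image.max() - image
    if threshold_method == "fixed":
        if threshold is None:
            raise ValueError("fixed threshold_method requires a threshold value")
        level = threshold
    elif threshold_method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError("blank image: no droplet found")
        level = threshold_otsu(image)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    mask = image > level
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValueError("no component found above threshold")
    regions = sorted(measure.regionprops(labels), key=lambda r: r.area, reverse=True)
    if regions[0].area < min_area_px:
        raise ValueError(f"largest component ({regions[0].area} px) below minimum area")
    if len(regions) > 1 and regions[1].area >= min_area_px:
        logger.warning("multiple droplets detected; keeping the largest")
    keep = labels == regions[0].label

    contours = measure.find_contours(keep.astype(float), 0.5)
    contour = max(contours, key=len)
    if smooth_sigma > 0:
        contour = np.column_stack(
            [
                gaussian_filter1d(contour[:, 0], smooth_sigma, mode="wrap"),
                gaussian_filter1d(contour[:, 1], smooth_sigma, mode="wrap"),
            ]
        )
    return contour


def detect_baseline(
    contour: np.ndarray,
    mode: str = "auto",
    fixed_row: float | None = None,
    flat_tolerance_px: float = 1.5,
    min_run_fraction: float = 0.3,
) -> float:
    """Find the substrate row the droplet rests on.

    Auto mode looks for an extended horizontal flat run at the bottom of
    the contour (the contact line of a droplet on a level substrate) and
    returns its mean row. Tilted substrates have no such run and raise,
    pointing to ``fixed_row`` mode.
    """
    contour = np.asarray(contour, dtype=float)
    if mode == "fixed_row":
        if fixed_row is None:
            raise ValueError("fixed_row mode requires a row value")
        if contour[:, 0].max() < fixed_row - 2:
            raise ValueError("contour lies entirely above the supplied baseline row")
        return float(fixed_row)
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")

    bottom = contour[:, 0].max()
    near_bottom = contour[np.abs(contour[:, 0] - bottom) <= flat_tolerance_px]
    run_width = np.ptp(near_bottom[:, 1])
    droplet_width = np.ptp(contour[:, 1])
    if run_width < min_run_fraction * droplet_width:
        raise ValueError(
            "no extended flat run at the contour bottom (tilted substrate?); "
            "use mode='fixed_row' with a known baseline"
        )
    return float(near_bottom[:, 0].mean())


def _fit_circle(points: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit; returns (row_c, col_c, radius)."""
    r, c = points[:, 0], points[:, 1]
    a_mat = np.column_stack([r, c, np.ones_like(r)])
    b_vec = r**2 + c**2
    sol, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    rc, cc = sol[0] / 2.0, sol[1] / 2.0
    rad_sq = sol[2] + rc**2 + cc**2
    if rad_sq <= 0:
        raise np.linalg.LinAlgError("degenerate circle fit")
    return float(rc), float(cc), float(np.sqrt(rad_sq))


def _contact_points(contour: np.ndarray, baseline_row: float) -> tuple[np.ndarray, np.ndarray]:
    near = contour[np.abs(contour[:, 0] - baseline_row) <= 2.0]
    if near.size == 0:
        raise ValueError("contour does not intersect the baseline at two points")
    left = near[np.argmin(near[:, 1])]
    right = near[np.argmax(near[:, 1])]
    if right[1] - left[1] < 4:
        raise ValueError("contour does not intersect the baseline at two points")
    return left, right


def measure_contact_angles(
    contour: np.ndarray,
    baseline_row: float,
    method: str = "circle_fit",
    tangent_window_px: float = 40.0,
) -> ContactAngleResult:
    """Interior contact angles where the droplet surface meets the baseline.

    ``circle_fit`` fits a circle to the contour above the baseline; the
    interior angle at each contact point is arccos((row_c - baseline) / R)
    (90 degrees when the center sits on the baseline). ``polynomial_tangent``
    fits a local quadratic x(h) of column against height above the baseline
    near each contact point and converts its slope to an angle; it handles
    non-circular surfaces and angles beyond 90 degrees without assuming a
    cap shape. A degenerate circle fit falls back to the polynomial method
    with a warning.
    """
    contour = np.asarray(contour, dtype=float)
    left, right = _contact_points(contour, baseline_row)

    if method == "circle_fit":
        above = contour[contour[:, 0] < baseline_row - 1.0]
        if above.shape[0] < 10:
            raise ValueError("too few contour points above the baseline")
        try:
            rc, cc, radius = _fit_circle(above)
            cos_theta = np.clip((rc - baseline_row) / radius, -1.0, 1.0)
            theta = float(np.degrees(np.arccos(cos_theta)))
            theta_left = theta_right = theta
            # circle-baseline intersections as contact points
            half_chord = radius**2 - (rc - baseline_row) ** 2
            if half_chord > 0:
                hw = float(np.sqrt(half_chord))
                left = np.array([baseline_row, cc - hw])
                right = np.array([baseline_row, cc + hw])
        except np.linalg.LinAlgError:
            logger.warning("degenerate circle fit; falling back to polynomial_tangent")
            return measure_contact_angles(
                contour, baseline_row, "polynomial_tangent", tangent_window_px
            )
    elif method == "polynomial_tangent":
        theta_left = _tangent_angle(contour, baseline_row, left, "left", tangent_window_px)
        theta_right = _tangent_angle(contour, baseline_row, right, "right", tangent_window_px)
    else:
        raise ValueError(f"unknown method {method!r}")

    return ContactAngleResult(
        theta_left=theta_left,
        theta_right=theta_right,
        theta_mean=0.5 * (theta_left + theta_right),
        baseline_row=float(baseline_row),
        contact_points=(tuple(left), tuple(right)),
        method=method,
    )


def _tangent_angle(
    contour: np.ndarray,
    baseline_row: float,
    contact: np.ndarray,
    side: str,
    window_px: float,
) -> float:
    """Angle from a local quadratic of column vs height above the baseline.

    Parametrizing column as a function of height is single-valued near the
    contact point for any angle in (0, 180), unlike height-vs-column which
    breaks down past 90 degrees.
    """
    height = baseline_row - contour[:, 0]
    mid_col = contour[:, 1].mean()
    on_side = contour[:, 1] < mid_col if side == "left" else contour[:, 1] > mid_col
    # skip the corner-adjacent points: contour smoothing rounds the junction
    # between the droplet surface and the substrate run, bending tangents there.
    # The window scales with cap height so apex points (where the quadratic in
    # height breaks down) stay out of the fit; accuracy is ~5 degrees, the
    # circle fit being the accurate choice for near-spherical droplets.
    cap_height = baseline_row - contour[:, 0].min()
    window = float(np.clip(0.35 * cap_height, 8.0, window_px))
    local = (height >= 4.0) & (height <= window) & on_side
    pts = contour[local]
    if pts.shape[0] < 5:
        raise ValueError(f"too few contour points near the {side} contact point")
    h = baseline_row - pts[:, 0]
    coeffs = np.polyfit(h, pts[:, 1], 2)
    slope = float(np.polyval(np.polyder(coeffs), 0.0))  # d(col)/d(height) at baseline
    if side == "right":
        slope = -slope
    return float(np.degrees(np.arctan2(1.0, slope)))


def circularity(mask: np.ndarray, smooth_sigma: float = 2.0) -> CircularityResult:
    """Circularity 4*pi*A/P^2 of a binary top-view droplet mask.

    The perimeter is the arc length of the Gaussian-smoothed marching-
    squares contour (raw pixel-edge perimeters overestimate by up to ~11%);
    the area is the shoelace area of the same contour, keeping the two
    consistent. A disc scores ~1, a square pi/4.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    labels = measure.label(mask)
    if labels.max() != 1:
        raise ValueError(f"mask must contain exactly one component, found {labels.max()}")

    contour = max(measure.find_contours(mask.astype(float), 0.5), key=len)
    if smooth_sigma > 0:
        contour = np.column_stack(
            [
                gaussian_filter1d(contour[:, 0], smooth_sigma, mode="wrap"),
                gaussian_filter1d(contour[:, 1], smooth_sigma, mode="wrap"),
            ]
        )
    closed = np.vstack([contour, contour[:1]])
    seg = np.diff(closed, axis=0)
    perimeter = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    r, c = closed[:, 0], closed[:, 1]
    area = float(abs(np.sum(r[:-1] * c[1:] - r[1:] * c[:-1])) / 2.0)
    return CircularityResult(
        circularity=4.0 * np.pi * area / perimeter**2,
        area=area,
        perimeter=perimeter,
    )
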