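"""Tabular assay calculators: CFU, viability, rheology, recipe arithmetic.

Covers the bookkeeping arithmetic of the hydrogel characterization assays:
colony-forming-unit estimation from single-plate serial-dilution spotting
(SP-SDS), Live/Dead viability with a minimal fluorescent-spot counter,
oscillatory-rheology loss tangent and linear-viscoelastic-region detection,
hydrogel recipe volume calculation, and a stain molarity helper.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpotCountTable",
    "CfuResult",
    "FrequencySweep",
    "RecipeSpec",
    "cfu_per_ml",
    "viability",
    "count_cells",
    "loss_tangent",
    "lve_region",
    "recipe",
    "ug_per_ml_to_mM",
]


@dataclass
class SpotCountTable:
    """Colony counts from spot-plated serial dilutions.

    Row i holds the count observed after spotting ``spot_volume_ml[i]`` of
    the 10^-``dilution_exponent[i]`` dilution.
    """

    dilution_exponent: np.ndarray
    spot_volume_ml: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.dilution_exponent = np.asarray(self.dilution_exponent, dtype=int)
        self.spot_volume_ml = np.asarray(self.spot_volume_ml, dtype=float)
        self.count = np.asarray(self.count)
        n = self.dilution_exponent.size
        if self.spot_volume_ml.size != n or self.count.size != n:
            raise ValueError("columns must have equal length")
        if n == 0:
            raise ValueError("table is empty")
        for i in range(n):
            if self.dilution_exponent[i] < 0:
                raise ValueError(f"row {i}: dilution_exponent must be >= 0")
            if self.spot_volume_ml[i] <= 0:
                raise ValueError(f"row {i}: spot_volume_ml must be > 0")
            c = self.count[i]
            if c < 0 or c != int(c):
                raise ValueError(f"row {i}: count must be a non-negative integer")
        self.count = self.count.astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dilution_exponent": self.dilution_exponent,
                "spot_volume_ml": self.spot_volume_ml,
                "count": self.count,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpotCountTable":
        return cls(
            dilution_exponent=df["dilution_exponent"].to_numpy(),
            spot_volume_ml=df["spot_volume_ml"].to_numpy(),
            count=df["count"].to_numpy(),
        )


@dataclass
class CfuResult:
    """CFU/ml estimate with countable-range bookkeeping.

    ``censored`` is set when no dilution fell in the countable range; the
    estimate is then 0 with ``detection_limit`` giving the smallest
    abundance the most dilute spot could have detected.
    """

    cfu_per_ml: float
    usable_rows: np.ndarray
    censored: bool
    detection_limit: float | None = None
    per_row_estimates: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class FrequencySweep:
    """Oscillatory rheology frequency sweep: G'(w) storage, G''(w) loss moduli."""

    omega: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.g_prime = np.asarray(self.g_prime, dtype=float)
        self.g_double_prime = np.asarray(self.g_double_prime, dtype=float)
        if self.omega.size == 0:
            raise ValueError("sweep is empty")
        if np.any(self.omega <= 0) or np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be positive and strictly increasing")
        if self.g_prime.size != self.omega.size or self.g_double_prime.size != self.omega.size:
            raise ValueError("moduli must match omega in length")
        if np.any(self.g_prime < 0) or np.any(self.g_double_prime < 0):
            raise ValueError("moduli must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "omega_rad_s": self.omega,
                "g_prime_pa": self.g_prime,
                "g_double_prime_pa": self.g_double_prime,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrequencySweep":
        return cls(
            omega=df["omega_rad_s"].to_numpy(),
            g_prime=df["g_prime_pa"].to_numpy(),
            g_double_prime=df["g_double_prime_pa"].to_numpy(),
        )


@dataclass(frozen=True)
class RecipeSpec:
    """Hydrogel recipe: dilute alginate and mucin stocks to target w/v
    percentages, with crosslinker solution making up a fixed fraction of the
    final volume and PBS as the balance."""

    total_volume_ul: int = 900
    alginate_stock_pct: float = 3.0
    alginate_target_pct: float = 1.0
    mucin_stock_pct: float = 10.0
    mucin_target_pct: float = 0.0
    cacl2_stock_mM: float = 11.0
    cacl2_fraction_of_total: float = 0.5

    def __post_init__(self) -> None:
        if self.total_volume_ul <= 0:
            raise ValueError("total_volume_ul must be > 0")
        if self.alginate_target_pct < 0 or self.mucin_target_pct < 0:
            raise ValueError("target percentages must be >= 0")
        if self.alginate_stock_pct < self.alginate_target_pct:
            raise ValueError("alginate stock weaker than target")
        if self.mucin_target_pct > 0 and self.mucin_stock_pct < self.mucin_target_pct:
            raise ValueError("mucin stock weaker than target")
        if not 0 <= self.cacl2_fraction_of_total <= 1:
            raise ValueError("cacl2_fraction_of_total must lie in [0, 1]")


def cfu_per_ml(
    table: SpotCountTable,
    countable_min: int = 6,
    countable_max: int = 60,
    mode: str = "mean",
) -> CfuResult:
    """Estimate CFU/ml from spot-plated serial-dilution counts.

    Rows whose count lies in the countable range [countable_min,
    countable_max] are each converted to count / (spot_volume * 10^-exponent)
    and averaged (``mode="mean"``); ``mode="most_dilute"`` instead keeps the
    single usable row at the highest dilution. With no usable row the result
    is censored: 0 CFU/ml with the detection limit of the most dilute spot.
    """
    if mode not in ("mean", "most_dilute"):
        raise ValueError(f"unknown mode {mode!r}")
    usable = (table.count >= countable_min) & (table.count <= countable_max)
    if not usable.any():
        max_exp = int(table.dilution_exponent.max())
        vol = float(table.spot_volume_ml[np.argmax(table.dilution_exponent)])
        limit = countable_min / (vol * 10.0 ** (-max_exp))
        return CfuResult(0.0, np.flatnonzero(usable), True, detection_limit=limit)

    idx = np.flatnonzero(usable)
    est = table.count[idx] / (
        table.spot_volume_ml[idx] * 10.0 ** (-table.dilution_exponent[idx].astype(float))
    )
    if mode == "most_dilute":
        pick = np.argmax(table.dilution_exponent[idx])
        return CfuResult(float(est[pick]), idx[[pick]], False, per_row_estimates=est[[pick]])
    return CfuResult(float(est.mean()), idx, False, per_row_estimates=est)


def viability(total_cells: int, dead_cells: int) -> float:
    """Live/Dead viability: 100 * (total - dead) / total, percent."""
    if total_cells <= 0:
        raise ValueError("total_cells must be > 0 (viability undefined)")
    if dead_cells < 0 or dead_cells > total_cells:
        raise ValueError("dead_cells must lie in [0, total_cells]")
    return 100.0 * (total_cells - dead_cells) / total_cells


def count_cells(
    nuclei_image: np.ndarray,
    dead_image: np.ndarray,
    match_radius_px: float = 5.0,
    spot_sigma: float = 3.0,
    min_distance_px: int = 5,
    threshold_rel: float = 0.2,
) -> tuple[int, int]:
    """Count nuclei and dead cells in co-registered fluorescence images.

    A minimal spot counter: band-pass (difference of Gaussians at
    ``spot_sigma`` and 2x) then local maxima with a minimum separation and
    relative intensity threshold. Dead-channel spots are matched to the
    nearest nucleus within ``match_radius_px``; unmatched dead spots are
    ignored (debris). Returns ``(total, dead)`` for :func:`viability`.
    """
    from scipy.ndimage import gaussian_filter
    from scipy.spatial import cKDTree
    from skimage.feature import peak_local_max

    nuclei_image = np.asarray(nuclei_image, dtype=float)
    dead_image = np.asarray(dead_image, dtype=float)
    if nuclei_image.shape != dead_image.shape:
        raise ValueError("nuclei and dead images must have the same shape")

    def detect(img: np.ndarray) -> np.ndarray:
        band = gaussian_filter(img, spot_sigma) - gaussian_filter(img, 2 * spot_sigma)
        if band.max() <= 0:
            return np.empty((0, 2))
        return peak_local_max(
            band,
            min_distance=min_distance_px,
            threshold_abs=threshold_rel * band.max(),
        )

    nuclei = detect(nuclei_image)
    dead = detect(dead_image)
    if nuclei.shape[0] == 0:
        return 0, 0
    if dead.shape[0] == 0:
        return int(nuclei.shape[0]), 0
    dist, _ = cKDTree(nuclei).query(dead)
    return int(nuclei.shape[0]), int(np.sum(dist <= match_radius_px))


def loss_tangent(
    sweep: FrequencySweep,
    query_omega: np.ndarray | list | None = None,
    match_tolerance: float = 0.05,
    interpolate: bool = False,
) -> pd.DataFrame:
    """Loss tangent tan(delta) = G''/G' at each frequency of a sweep.

    When ``query_omega`` is given, each query is answered by the nearest
    grid point within ``match_tolerance`` relative distance (mirroring how
    one reads values off an instrument grid), or by linear interpolation
    when ``interpolate=True``. Returns a DataFrame with columns
    ``omega_rad_s``, ``tan_delta`` and ``method``.
    """
    if query_omega is None:
        if np.any(sweep.g_prime <= 0):
            raise ValueError("G' = 0 in sweep: tan(delta) undefined")
        return pd.DataFrame(
            {
                "omega_rad_s": sweep.omega,
                "tan_delta": sweep.g_double_prime / sweep.g_prime,
                "method": "grid",
            }
        )

    rows = []
    for w in np.atleast_1d(np.asarray(query_omega, dtype=float)):
        if interpolate:
            gp = float(np.interp(w, sweep.omega, sweep.g_prime))
            gpp = float(np.interp(w, sweep.omega, sweep.g_double_prime))
            method = "interpolated"
        else:
            i = int(np.argmin(np.abs(sweep.omega - w)))
            if abs(sweep.omega[i] - w) > match_tolerance * w:
                raise ValueError(
                    f"no grid point within {match_tolerance:.0%} of omega={w}"
                    " (pass interpolate=True to interpolate)"
                )
            gp, gpp = float(sweep.g_prime[i]), float(sweep.g_double_prime[i])
            method = "nearest"
        if gp <= 0:
            raise ValueError(f"G' = 0 at omega={w}: tan(delta) undefined")
        rows.append({"omega_rad_s": w, "tan_delta": gpp / gp, "method": method})
    return pd.DataFrame(rows)


def lve_region(
    strain_pct: np.ndarray,
    g_prime: np.ndarray,
    tolerance: float = 0.05,
) -> tuple[float, float]:
    """Linear viscoelastic region of a strain sweep.

    The plateau modulus is the median G' over the lowest decade of strain;
    the LVE region is the maximal initial run of strains whose G' stays
    within ``tolerance`` (fractional) of that plateau. Returns the (min,
    max) strain of the region in percent.
    """
    strain_pct = np.asarray(strain_pct, dtype=float)
    g_prime = np.asarray(g_prime, dtype=float)
    if strain_pct.size < 5:
        raise ValueError("need at least 5 strain points")
    if np.any(np.diff(strain_pct) <= 0):
        raise ValueError("strains must be strictly increasing")
    low_decade = strain_pct <= 10.0 * strain_pct[0]
    plateau = float(np.median(g_prime[low_decade]))
    within = np.abs(g_prime - plateau) <= tolerance * plateau
    if not within[0]:
        raise ValueError("no initial plateau: G' deviates from the first point on")
    # maximal initial run
    end = int(np.argmin(within)) if not within.all() else within.size
    return float(strain_pct[0]), float(strain_pct[end - 1])


def recipe(spec: RecipeSpec) -> dict:
    """Component volumes (integer ul) for an alginate-mucin hydrogel.

    The crosslinker (CaCl2 in medium) makes up ``cacl2_fraction_of_total``
    of the final volume (default half); alginate and mucin stocks are
    diluted as total * target / stock; PBS absorbs the balance and any
    integer-microliter rounding remainder, so the volumes always sum to the
    total exactly. The final crosslinker concentration is stock * fraction.
    """
    total = spec.total_volume_ul
    alg = int(round(total * spec.alginate_target_pct / spec.alginate_stock_pct))
    muc = (
        int(round(total * spec.mucin_target_pct / spec.mucin_stock_pct))
        if spec.mucin_target_pct > 0
        else 0
    )
    cacl2 = int(round(total * spec.cacl2_fraction_of_total))
    pbs = total - alg - muc - cacl2
    if pbs < 0:
        max_muc_pct = (
            (total - alg - cacl2) / total * spec.mucin_stock_pct
        )
        raise ValueError(
            "targets over-constrained: PBS volume would be negative "
            f"(maximum feasible mucin target {max_muc_pct:.2f}% w/v)"
        )
    return {
        "alginate_stock_ul": alg,
        "pbs_ul": pbs,
        "mucin_stock_ul": muc,
        "cacl2_solution_ul": cacl2,
        "total_ul": alg + pbs + muc + cacl2,
        "final_cacl2_mM": spec.cacl2_stock_mM * spec.cacl2_fraction_of_total,
    }


def ug_per_ml_to_mM(concentration_ug_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration to millimolar given the molar mass.

    ug/ml equals mg/l, so mM = (ug/ml) / (g/mol). Used for stain
    bookkeeping, e.g. Hoechst at 5 ug/ml and 616 g/mol is 8.1e-3 mM.
    """
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be > 0")
    if concentration_ug_per_ml < 0:
        raise ValueError("concentration must be >= 0")
    return concentration_ug_per_ml / molar_mass_g_per_mol
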