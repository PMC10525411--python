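"""Suitability thresholding, land-use area accounting, and latitude profiles.

Suitability maps are cut at a fixed threshold into potential geographic
distribution (PGD) vs non-PGD cells; areas are computed on the sphere with
latitude-dependent cell sizes and weighted by per-cell ecosystem fractions,
giving Table-style per-ecosystem PGD areas, gain/loss change maps between
scenarios, and latitudinal suitability profiles with fitted peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import EcosystemFractions, GridAlignmentError, GridSpec, RasterGrid

__all__ = [
    "PGDMap",
    "ChangeMap",
    "LatitudeProfile",
    "threshold_pgd",
    "cell_areas",
    "ecosystem_pgd_area",
    "change_map",
    "latitudinal_profile",
    "proportion_percent",
    "peak_shift",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0

# integer codes for map serialization
PGD, NON_PGD, NODATA = 1, 0, -1
GAIN, LOSS, STABLE, NEVER = 2, 3, 1, 0


@dataclass
class PGDMap:
    """Binary suitability classification at a recorded cutoff."""

    spec: GridSpec
    state: np.ndarray  # int8: PGD / NON_PGD / NODATA
    cutoff: float

    @property
    def pgd_mask(self) -> np.ndarray:
        return self.state == PGD

    @property
    def data_mask(self) -> np.ndarray:
        return self.state != NODATA


@dataclass
class ChangeMap:
    """Cellwise transition between a reference and a future PGD map."""

    spec: GridSpec
    state: np.ndarray  # GAIN / LOSS / STABLE / NEVER / NODATA
    meta: dict


@dataclass
class LatitudeProfile:
    """Banded latitudinal suitability with per-hemisphere fitted peaks."""

    band_centers: np.ndarray
    mean_suitability: np.ndarray  # NaN where a band has no weight
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    peak_latitude: dict[str, float | None]  # "north"/"south"; None if undefined
    fit_degree: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "band_center": self.band_centers,
                "mean_suitability": self.mean_suitability,
                "fitted": self.fitted,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


# ---------------------------------------------------------------------------


def threshold_pgd(
    suitability: RasterGrid, cutoff: float = 0.23, strict: bool = True
) -> PGDMap:
    """Cut a suitability raster into PGD / non-PGD cells.

    With ``strict`` (default), a cell exactly at the cutoff is non-PGD
    (the PGD interval is the open-below ``(cutoff, 1]``); the flag flips the
    boundary for sensitivity analysis.
    """
    vals = suitability.values
    finite = np.isfinite(vals)
    if finite.any() and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
        raise ValueError("suitability values must lie in [0, 1]")
    state = np.full(vals.shape, NODATA, dtype=np.int8)
    above = vals > cutoff if strict else vals >= cutoff
    state[finite & above] = PGD
    state[finite & ~above] = NON_PGD
    return PGDMap(suitability.spec, state, cutoff)


def cell_areas(spec: GridSpec) -> RasterGrid:
    """Spherical cell areas in square kilometres.

    area(row) = R^2 * dlon * (sin(lat_top) - sin(lat_bottom)); identical
    along a row.
    """
    lat_top = np.deg2rad(spec.north - np.arange(spec.n_rows) * spec.cell_deg)
    lat_bot = lat_top - np.deg2rad(spec.cell_deg)
    dlon = np.deg2rad(spec.cell_deg)
    row_area = EARTH_RADIUS_KM**2 * dlon * (np.sin(lat_top) - np.sin(lat_bot))
    values = np.repeat(row_area[:, None], spec.n_cols, axis=1)
    return RasterGrid(spec, values, "cell_area_km2")


def ecosystem_pgd_area(
    pgd: PGDMap,
    fractions: EcosystemFractions,
    scenario: str = "near_current",
    period: str = "",
) -> pd.DataFrame:
    """Fraction-weighted PGD area per ecosystem.

    For each ecosystem: total area is the sum of cell_area * fraction over
    data cells; PGD area is the same sum over PGD cells; proportion is their
    ratio in percent.
    """
    if fractions.forest.spec != pgd.spec:
        raise GridAlignmentError("PGD map and land-use fractions are not co-registered")
    areas = cell_areas(pgd.spec).values
    rows = []
    for eco, grid in fractions.as_dict().items():
        w = np.nan_to_num(grid.values) * areas
        data = pgd.data_mask & np.isfinite(grid.values)
        total = float(w[data].sum())
        in_pgd = float(w[data & pgd.pgd_mask].sum())
        rows.append(
            {
                "scenario": scenario,
                "period": period,
                "ecosystem": eco,
                "pgd_area_km2": in_pgd,
                "total_area_km2": total,
                "proportion_pct": 100.0 * in_pgd / total if total > 0 else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    # Table-style units alongside the raw square kilometres
    df["pgd_area_1e4km2"] = df["pgd_area_km2"] / 1e4
    df["total_area_1e4km2"] = df["total_area_km2"] / 1e4
    return df


def proportion_percent(pgd_area: float, total_area: float) -> int:
    """PGD share of an ecosystem as a rounded integer percentage."""
    if total_area <= 0:
        raise ValueError("total area must be positive")
    return int(round(100.0 * pgd_area / total_area))


def change_map(
    pgd_ref: PGDMap,
    pgd_future: PGDMap,
    fractions: EcosystemFractions | None = None,
) -> tuple[ChangeMap, pd.DataFrame]:
    """Cellwise gain/loss/stable/never transitions plus area accounting.

    Returns the change map and a per-ecosystem (or whole-grid) gain/loss
    area table in square kilometres.
    """
    if pgd_ref.spec != pgd_future.spec:
        raise GridAlignmentError("PGD maps are not co-registered")
    meta = {"cutoff_ref": pgd_ref.cutoff, "cutoff_future": pgd_future.cutoff}
    if pgd_ref.cutoff != pgd_future.cutoff:
        warnings.warn("PGD maps use different cutoffs; change map may be inconsistent")
        meta["cutoff_mismatch"] = True
    state = np.full(pgd_ref.state.shape, NODATA, dtype=np.int8)
    data = pgd_ref.data_mask & pgd_future.data_mask
    ref, fut = pgd_ref.pgd_mask, pgd_future.pgd_mask
    state[data & ~ref & fut] = GAIN
    state[data & ref & ~fut] = LOSS
    state[data & ref & fut] = STABLE
    state[data & ~ref & ~fut] = NEVER
    areas = cell_areas(pgd_ref.spec).values
    rows = []
    if fractions is None:
        weights = {"all": np.ones_like(areas)}
    else:
        weights = {eco: np.nan_to_num(g.values) for eco, g in fractions.as_dict().items()}
    for eco, w in weights.items():
        wa = w * areas
        rows.append(
            {
                "ecosystem": eco,
                "gain_km2": float(wa[state == GAIN].sum()),
                "loss_km2": float(wa[state == LOSS].sum()),
                "stable_km2": float(wa[state == STABLE].sum()),
            }
        )
    return ChangeMap(pgd_ref.spec, state, meta), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# latitudinal profiles

#: fitted curves whose total variation is below this are treated as flat
FLATNESS_TOL = 1e-6


def _fit_hemisphere(
    centers: np.ndarray, means: np.ndarray, degree: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float | None]:
    """Polynomial least squares with pointwise 95% band; returns fit, CI, peak."""
    ok = np.isfinite(means)
    fitted = np.full_like(means, np.nan, dtype=float)
    lo = np.full_like(means, np.nan, dtype=float)
    hi = np.full_like(means, np.nan, dtype=float)
    if ok.sum() < degree + 2:
        return fitted, lo, hi, None
    x = centers[ok]
    # center/scale the abscissa for conditioning
    x0, xs = x.mean(), max(x.std(), 1e-9)
    X = np.vander((x - x0) / xs, degree + 1, increasing=True)
    res = sm.OLS(means[ok], X).fit()
    pred = res.get_prediction(X)
    fitted[ok] = pred.predicted_mean
    band = pred.conf_int(alpha=0.05)
    lo[ok], hi[ok] = band[:, 0], band[:, 1]
    if np.ptp(fitted[ok]) < FLATNESS_TOL:
        return fitted, lo, hi, None
    # continuous argmax of the fitted polynomial over the observed span
    fine = np.linspace(x.min(), x.max(), max(10 * len(x), 1000))
    Xf = np.vander((fine - x0) / xs, degree + 1, increasing=True)
    peak = float(fine[np.argmax(Xf @ res.params)])
    return fitted, lo, hi, peak


def latitudinal_profile(
    suitability: RasterGrid,
    fraction: RasterGrid | None = None,
    band_deg: float = 0.5,
    fit_degree: int = 2,
) -> LatitudeProfile:
    """Ecosystem-weighted mean suitability in latitude bands with fitted peaks.

    Bands are half-open ``[lo, lo + band_deg)`` tiling [-90, 90]; the mean in
    each band weights cells by spherical area times the ecosystem fraction.
    A polynomial of ``fit_degree`` is fitted per hemisphere with a pointwise
    95% confidence band, and the peak latitude is the continuous argmax of
    the fitted curve (None when the hemisphere is empty or flat).
    """
    spec = suitability.spec
    if fraction is not None:
        if fraction.spec != spec:
            raise GridAlignmentError("fraction layer is not co-registered")
        frac = np.nan_to_num(fraction.values)
        if frac.min() < -1e-9 or frac.max() > 1 + 1e-9:
            raise ValueError("fractions must lie in [0, 1]")
    else:
        frac = np.ones((spec.n_rows, spec.n_cols))
    areas = cell_areas(spec).values
    w = np.where(np.isfinite(suitability.values), frac * areas, 0.0)
    s = np.nan_to_num(suitability.values)
    lat = spec.lat_centers()
    edges = np.arange(-90.0, 90.0 + band_deg / 2, band_deg)
    centers = edges[:-1] + band_deg / 2
    band_idx = np.clip(((lat + 90.0) / band_deg).astype(int), 0, len(centers) - 1)
    wsum = np.zeros(len(centers))
    swsum = np.zeros(len(centers))
    np.add.at(wsum, band_idx, w.sum(axis=1))
    np.add.at(swsum, band_idx, (w * s).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(wsum > 0, swsum / wsum, np.nan)
    fitted = np.full_like(means, np.nan)
    lo = np.full_like(means, np.nan)
    hi = np.full_like(means, np.nan)
    peaks: dict[str, float | None] = {}
    for hemi, sel in (("south", centers < 0), ("north", centers > 0)):
        f, l, h, peak = _fit_hemisphere(
            np.abs(centers[sel]), means[sel], fit_degree
        )
        fitted[sel], lo[sel], hi[sel] = f, l, h
        peaks[hemi] = peak
    return LatitudeProfile(centers, means, fitted, lo, hi, peaks, fit_degree)


def peak_shift(peak_reference: float, peak_future: float, decimals: int = 1) -> float:
    """Poleward displacement of a fitted suitability peak, in degrees."""
    return float(round(peak_future - peak_reference, decimals))
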