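"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Everything here is a pure function of its seed and parameters: bioclim-like
rasters (latitudinal gradient plus spatially smoothed noise), virtual
species with known multiplicative-Gaussian suitability, paired native /
invaded ranges with a programmable niche shift, LUH2-style land-use
fraction fields, and logistic invasion timelines.  These generators define
the study conditions for the test suite; they are not tuned per test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import (
    DEFAULT_STATE_MAPPING,
    EcosystemFractions,
    GridSpec,
    LayerStack,
    RasterGrid,
    aggregate_landuse,
)
from .occurrences import CountryFirstRecord, OccurrenceTable
from .overlay import cell_areas

__all__ = [
    "DEFAULT_WORLD",
    "VirtualSpeciesConfig",
    "NicheShiftScenario",
    "make_climate_stack",
    "default_virtual_species",
    "make_true_suitability",
    "sample_presences",
    "make_shifted_ranges",
    "make_landuse",
    "make_timeline",
]

#: default synthetic world: 50 x 50 half-degree cells spanning both
#: hemispheres (lat -12.5..12.5, lon -25..0)
DEFAULT_WORLD = GridSpec(n_rows=50, n_cols=50, west=-25.0, north=12.5, cell_deg=0.5)

#: value ranges the generated layers are rescaled to, cycled over layers;
#: the first mimics an annual-mean-temperature bioclim layer, the second an
#: annual-precipitation layer
LAYER_RANGES: tuple[tuple[float, float], ...] = (
    (-10.0, 30.0),
    (0.0, 3000.0),
    (0.0, 100.0),
    (10.0, 45.0),
    (0.0, 400.0),
)


@dataclass(frozen=True)
class VirtualSpeciesConfig:
    """Known ground-truth response of a simulated species.

    ``response_optima`` / ``response_breadths`` map covariate name to the
    optimum and Gaussian breadth (SD) of the species' response in covariate
    units; suitability is the product of the per-covariate Gaussians.
    """

    response_optima: dict[str, float]
    response_breadths: dict[str, float]
    n_presence: int = 300
    sampling: str = "probability_weighted"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_presence < 1:
            raise ValueError("n_presence must be >= 1")
        if any(b <= 0 for b in self.response_breadths.values()):
            raise ValueError("response breadths must be positive")
        if set(self.response_optima) != set(self.response_breadths):
            raise ValueError("optima and breadths must cover the same covariates")
        if self.sampling not in {"bernoulli", "probability_weighted"}:
            raise ValueError("sampling must be 'bernoulli' or 'probability_weighted'")


@dataclass(frozen=True)
class NicheShiftScenario:
    """Controlled displacement of the invaded range's niche.

    ``shift_magnitude`` displaces the invaded-range optima in units of the
    pooled (suitability-weighted) standard deviation of each covariate over
    the occupied cells — the realized-niche scale, so a shift of a few units
    moves the niche decisively while staying inside analog environments;
    ``background_offset`` separates the two extents geographically (in
    longitude columns).
    """

    shift_magnitude: float = 0.0
    background_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift_magnitude < 0:
            raise ValueError("shift magnitude must be non-negative")


# ---------------------------------------------------------------------------
# climate layers


def make_climate_stack(
    spec: GridSpec = DEFAULT_WORLD,
    n_vars: int = 5,
    seed: int = 0,
    gradient_weight: float = 0.6,
    noise_smoothing: float = 2.0,
) -> LayerStack:
    """Bioclim-like covariate rasters: latitudinal gradient + smooth noise.

    Each layer is ``gradient_weight`` times a north-south gradient plus the
    complement times Gaussian noise smoothed with a ``noise_smoothing``-cell
    kernel, min-max rescaled to the layer's configured range.
    """
    if n_vars < 1:
        raise ValueError("need at least one layer")
    rng = np.random.default_rng(seed)
    lat = spec.lat_centers()
    # gradient decreasing from equator to poles, in [0, 1]
    gradient = 1.0 - np.abs(lat) / 90.0
    gradient_field = np.repeat(gradient[:, None], spec.n_cols, axis=1)
    stack = LayerStack()
    for v in range(n_vars):
        noise = rng.standard_normal((spec.n_rows, spec.n_cols))
        if noise_smoothing > 0:
            noise = gaussian_filter(noise, noise_smoothing, mode="nearest")
        if np.ptp(noise) > 0:
            noise = (noise - noise.min()) / np.ptp(noise)
        raw = gradient_weight * gradient_field + (1.0 - gradient_weight) * noise
        if np.ptp(raw) > 0:
            raw = (raw - raw.min()) / np.ptp(raw)
        lo, hi = LAYER_RANGES[v % len(LAYER_RANGES)]
        stack.add(RasterGrid(spec, lo + raw * (hi - lo), f"bio{v + 1}"))
    return stack


# ---------------------------------------------------------------------------
# virtual species


def default_virtual_species(
    stack: LayerStack,
    optimum_quantile: float = 0.75,
    breadth_frac: float = 0.08,
    n_presence: int = 300,
    sampling: str = "probability_weighted",
    seed: int = 0,
) -> VirtualSpeciesConfig:
    """Canonical virtual species for a climate stack.

    Optima sit at the same quantile of every covariate, which places the
    niche coherently on the warm side of the shared latitudinal gradient (so
    programmed shifts move it along analog environments rather than off the
    climate manifold); breadths are a fixed fraction of each covariate's
    span, narrow enough that the realized niche does not fill the envelope.
    """
    optima: dict[str, float] = {}
    breadths: dict[str, float] = {}
    for name in stack.names:
        vals = stack[name].values
        optima[name] = float(np.nanquantile(vals, optimum_quantile))
        breadths[name] = breadth_frac * float(np.nanmax(vals) - np.nanmin(vals))
    return VirtualSpeciesConfig(
        response_optima=optima,
        response_breadths=breadths,
        n_presence=n_presence,
        sampling=sampling,
        seed=seed,
    )


def make_true_suitability(
    stack: LayerStack, config: VirtualSpeciesConfig, name: str = "true_suitability"
) -> RasterGrid:
    """Multiplicative-Gaussian suitability surface with known optima."""
    missing = [c for c in config.response_optima if c not in stack]
    if missing:
        raise KeyError(f"stack is missing covariates: {missing}")
    spec = stack.spec
    suit = np.ones((spec.n_rows, spec.n_cols))
    for cov, opt in config.response_optima.items():
        sd = config.response_breadths[cov]
        x = stack[cov].values
        suit = suit * np.exp(-((x - opt) ** 2) / (2.0 * sd**2))
    return RasterGrid(spec, suit, name)


def sample_presences(
    true_suitability: RasterGrid,
    config: VirtualSpeciesConfig,
    extent_mask: np.ndarray | None = None,
) -> OccurrenceTable:
    """Draw presence points from a known suitability surface.

    ``probability_weighted`` draws cells with probability proportional to
    suitability times spherical cell area; ``bernoulli`` draws uniform cells
    and accepts them with probability equal to the suitability.  Points are
    jittered uniformly within their cell so several presences can share a
    thinning cell.
    """
    spec = true_suitability.spec
    suit = np.nan_to_num(true_suitability.values).copy()
    if extent_mask is not None:
        suit = np.where(extent_mask, suit, 0.0)
    if suit.sum() <= 0:
        raise ValueError("suitability is zero everywhere in the extent")
    rng = np.random.default_rng(config.seed)
    n = config.n_presence
    rows_all, cols_all = np.nonzero(suit > 0)
    if config.sampling == "probability_weighted":
        w = suit * cell_areas(spec).values
        w = w[rows_all, cols_all]
        idx = rng.choice(len(rows_all), size=n, replace=True, p=w / w.sum())
    else:  # bernoulli
        picks: list[int] = []
        smax = suit[rows_all, cols_all].max()
        budget = 10_000 * n
        while len(picks) < n and budget > 0:
            cand = rng.integers(len(rows_all))
            budget -= 1
            if rng.random() <= suit[rows_all[cand], cols_all[cand]] / smax:
                picks.append(cand)
        if len(picks) < n:
            raise RuntimeError("bernoulli sampling failed to reach n_presence")
        idx = np.array(picks)
    r, c = rows_all[idx], cols_all[idx]
    lon = spec.west + (c + rng.random(n)) * spec.cell_deg
    lat = spec.north - (r + rng.random(n)) * spec.cell_deg
    df = pd.DataFrame({"longitude": lon, "latitude": lat, "source": "synthetic"})
    return OccurrenceTable(df)


# ---------------------------------------------------------------------------
# paired ranges with a programmed niche shift


def make_shifted_ranges(
    stack: LayerStack,
    config: VirtualSpeciesConfig,
    scenario: NicheShiftScenario,
) -> tuple[OccurrenceTable, OccurrenceTable, np.ndarray, np.ndarray]:
    """Native and invaded occurrence sets with a controlled niche shift.

    The grid is split into a western (native) and eastern (invaded) extent,
    separated by ``background_offset`` empty columns.  The invaded range's
    response optima are displaced by ``shift_magnitude`` pooled standard
    deviations of each covariate; shift 0 emulates a conserved niche.

    Returns (native table, invaded table, native extent mask, invaded
    extent mask).
    """
    spec = stack.spec
    half = spec.n_cols // 2
    gap = min(scenario.background_offset, half) // 2
    native_mask = np.zeros((spec.n_rows, spec.n_cols), dtype=bool)
    invaded_mask = np.zeros_like(native_mask)
    native_mask[:, : half - gap] = True
    invaded_mask[:, half + gap :] = True
    native_suit_all = make_true_suitability(stack, config, "native_suitability")
    shifted_optima = {}
    for cov, opt in config.response_optima.items():
        vals = stack[cov].values
        # displacement unit: pooled SD of the covariate over occupied cells
        # (suitability-weighted), i.e. the realized-niche scale -- so the
        # programmed shift stays inside analog environments where the COUE
        # indices are defined
        w = np.nan_to_num(native_suit_all.values).ravel()
        x = np.nan_to_num(vals).ravel()
        mu = float(np.average(x, weights=w))
        occ_sd = float(np.sqrt(np.average((x - mu) ** 2, weights=w)))
        # displace toward the side of the climate envelope with more room so
        # the shifted optimum stays attainable as long as possible
        direction = -1.0 if (opt - np.nanmin(vals)) > (np.nanmax(vals) - opt) else 1.0
        shifted_optima[cov] = opt + direction * scenario.shift_magnitude * occ_sd
    native_cfg = config
    invaded_cfg = VirtualSpeciesConfig(
        response_optima=shifted_optima,
        response_breadths=dict(config.response_breadths),
        n_presence=config.n_presence,
        sampling=config.sampling,
        seed=config.seed + 1 + scenario.seed,
    )
    native_suit = make_true_suitability(stack, native_cfg, "native_suitability")
    invaded_suit = make_true_suitability(stack, invaded_cfg, "invaded_suitability")
    native = sample_presences(native_suit, native_cfg, native_mask)
    invaded = sample_presences(invaded_suit, invaded_cfg, invaded_mask)
    return native, invaded, native_mask, invaded_mask


# ---------------------------------------------------------------------------
# land use


#: generated LUH2-style states; primn/secdn are deliberately left unmapped so
#: per-cell ecosystem sums stay below 1, as in real fraction layers
SYNTH_STATES: tuple[str, ...] = tuple(DEFAULT_STATE_MAPPING) + ("primn", "secdn")


def make_landuse(
    spec: GridSpec = DEFAULT_WORLD,
    seed: int = 0,
    concentration: float = 1.0,
) -> tuple[EcosystemFractions, LayerStack]:
    """Per-cell land-use state compositions from a symmetric Dirichlet.

    Returns the aggregated four-ecosystem fractions plus the raw state
    stack.  Concentration 1 gives uniform-simplex compositions; large
    concentrations give near-equal fractions.
    """
    rng = np.random.default_rng(seed)
    k = len(SYNTH_STATES)
    draws = rng.dirichlet(np.full(k, concentration), size=spec.n_rows * spec.n_cols)
    states = LayerStack()
    for j, name in enumerate(SYNTH_STATES):
        states.add(
            RasterGrid(spec, draws[:, j].reshape(spec.n_rows, spec.n_cols), name)
        )
    return aggregate_landuse(states), states


# ---------------------------------------------------------------------------
# invasion timeline


def make_timeline(
    n_countries: int = 41,
    start_year: int = 1950,
    end_year: int = 2023,
    midpoint: int = 1995,
    rate: float = 0.15,
    seed: int = 0,
    jitter: int = 2,
) -> list[CountryFirstRecord]:
    """Country first-record years following a logistic cumulative curve.

    The cumulative number of invaded countries tracks a logistic curve with
    the given midpoint and rate, normalized to the [start, end] window, with
    seeded integer jitter on each year.  ``rate -> 0`` degenerates to
    near-uniform yearly counts.
    """
    if end_year <= start_year:
        raise ValueError("end_year must exceed start_year")
    if n_countries < 1:
        raise ValueError("need at least one country")
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, end_year + 1)

    def sigma(y):
        return 1.0 / (1.0 + np.exp(-rate * (y - midpoint)))

    lo, hi = sigma(start_year), sigma(end_year)
    cdf = (sigma(years) - lo) / (hi - lo) if hi > lo else np.linspace(0, 1, len(years))
    records = []
    for i in range(n_countries):
        u = (i + 0.5) / n_countries
        year = int(years[np.searchsorted(cdf, u)])
        if jitter > 0:
            year += int(rng.integers(-jitter, jitter + 1))
        year = int(np.clip(year, start_year, end_year))
        records.append(CountryFirstRecord(f"country_{i:03d}", year))
    return records
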