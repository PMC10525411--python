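"""COUE niche-shift analysis in a two-axis environmental space.

The realized niches of two ranges (native and invaded) are compared on a
common principal-component plane:

1. Pool the background environments of both ranges, standardize, and take
   the first two principal components (``build_env_space``).
2. Grid the plane (R x R, default 100) and estimate each range's occupancy
   as a Gaussian kernel density of its occurrence scores, divided by the
   kernel density of its background scores — the availability-corrected
   occupancy (``occupancy_grid``).
3. Compare the two occupancy surfaces: Schoener's D, permutation-based
   equivalency and similarity tests, and the expansion / stability /
   unfilling decomposition.

Kernel bandwidths follow Silverman's rule per axis; kernels are truncated at
5 bandwidths so the grids contain exact zeros, which makes the
zero-occupancy sets in the dynamics indices well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .grids import LayerStack

__all__ = [
    "EnvSpace",
    "OccupancyGrid",
    "NicheComparison",
    "sample_background",
    "build_env_space",
    "occupancy_grid",
    "schoener_d",
    "equivalency_test",
    "similarity_test",
    "niche_dynamics",
    "compare_niches",
]

#: kernel support radius in bandwidth units
KERNEL_TRUNCATION = 5.0

#: background cells with density below this fraction of the max are outside the mask
MASK_THRESHOLD = 1e-3


@dataclass
class EnvSpace:
    """Two-axis PCA environmental space shared by both ranges."""

    mean: np.ndarray            # pooled covariate means
    sd: np.ndarray              # pooled covariate standard deviations
    axis_loadings: np.ndarray   # (2, n_covariates)
    explained_variance: np.ndarray  # 2 proportions
    grid_R: int = 100
    axis_bounds: np.ndarray | None = None  # (2, 2): per-axis (min, max)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Project raw covariate rows onto the two axes."""
        Z = (np.atleast_2d(np.asarray(X, float)) - self.mean) / self.sd
        return Z @ self.axis_loadings.T

    def grid_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates of the R x R occupancy grid."""
        (x0, x1), (y0, y1) = self.axis_bounds
        R = self.grid_R
        xs = x0 + (np.arange(R) + 0.5) * (x1 - x0) / R
        ys = y0 + (np.arange(R) + 0.5) * (y1 - y0) / R
        return xs, ys


@dataclass
class OccupancyGrid:
    """Occurrence density of one range on the environment grid.

    ``z`` is the availability-corrected occupancy (occurrence density over
    background density, zero where the background is too thin to divide by)
    and is what the overlap statistic D compares.  ``z_raw`` is the plain
    occurrence density; the dynamics indices use it because the correction
    ratio is numerically unstable exactly where expansion happens (rare
    environments).  ``support_mask`` marks every cell with any background
    density (the range's environmental envelope); ``background_mask`` is the
    stricter thresholded version used for the corrected surface and for
    relocating niches in the similarity test.
    """

    z: np.ndarray                # corrected, sums to 1
    z_raw: np.ndarray            # uncorrected occurrence density, sums to 1
    background_mask: np.ndarray  # thresholded availability mask
    support_mask: np.ndarray | None = None  # full envelope (bg density > 0)
    bg_density: np.ndarray | None = None    # kernel density of the background

    def __post_init__(self) -> None:
        if abs(self.z.sum() - 1.0) > 1e-8:
            raise ValueError("corrected occupancy must sum to 1")
        if self.support_mask is None:
            self.support_mask = self.background_mask


@dataclass
class NicheComparison:
    """Full COUE comparison between native and invaded realized niches."""

    D: float
    p_equivalency: float
    p_similarity: float
    expansion: float
    stability: float
    unfilling: float
    reps: int
    null_equivalency: np.ndarray | None = None
    null_similarity: np.ndarray | None = None

    def to_json_obj(self) -> dict:
        return {
            "schoener_D": self.D,
            "p_equivalency": self.p_equivalency,
            "p_similarity": self.p_similarity,
            "expansion": self.expansion,
            "stability": self.stability,
            "unfilling": self.unfilling,
            "reps": self.reps,
        }


# ---------------------------------------------------------------------------
# background sampling


def sample_background(
    stack: LayerStack,
    extent_mask: np.ndarray | None = None,
    n: int = 8000,
    lat_limit: float = 70.0,
    seed: int = 0,
):
    """Sample pseudo-absence points uniformly over a range's data cells.

    Cells are drawn without replacement from the complete-data cells of the
    extent whose centre latitude satisfies ``|lat| <= lat_limit``; each
    sampled point is the cell centre.  Returns a (k, 2) lon/lat array plus
    the (k, n_layers) covariate matrix.
    """
    spec = stack.spec
    mask = stack.complete_mask()
    if extent_mask is not None:
        mask = mask & np.asarray(extent_mask, bool)
    lat = spec.lat_centers()
    mask = mask & (np.abs(lat)[:, None] <= lat_limit)
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("extent has no eligible data cells")
    rng = np.random.default_rng(seed)
    if len(rows) < n:
        warnings.warn(
            f"only {len(rows)} eligible cells for {n} background points; using all"
        )
        take = np.arange(len(rows))
    else:
        take = rng.choice(len(rows), size=n, replace=False)
    r, c = rows[take], cols[take]
    lon = spec.lon_centers()[c]
    points = np.column_stack([lon, lat[r]])
    X = np.column_stack([stack[name].values[r, c] for name in stack.names])
    return points, X


# ---------------------------------------------------------------------------
# environment space


def build_env_space(
    native_bg_X: np.ndarray,
    invaded_bg_X: np.ndarray,
    grid_R: int = 100,
    pad: float = 0.1,
) -> EnvSpace:
    """PCA-env calibration on the pooled background environments."""
    native_bg_X = np.atleast_2d(np.asarray(native_bg_X, float))
    invaded_bg_X = np.atleast_2d(np.asarray(invaded_bg_X, float))
    if native_bg_X.shape[1] < 3:
        raise ValueError("need at least 3 covariates for the environment space")
    if min(len(native_bg_X), len(invaded_bg_X)) < 10:
        raise ValueError("need at least 10 background points per range")
    pooled = np.vstack([native_bg_X, invaded_bg_X])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    Z = (pooled - mean) / sd
    if np.linalg.matrix_rank(np.cov(Z.T)) < 2:
        raise ValueError("pooled environment has rank < 2; cannot build two axes")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z)
    span = scores.max(axis=0) - scores.min(axis=0)
    lo = scores.min(axis=0) - pad * span
    hi = scores.max(axis=0) + pad * span
    return EnvSpace(
        mean=mean,
        sd=sd,
        axis_loadings=pca.components_,
        explained_variance=pca.explained_variance_ratio_,
        grid_R=grid_R,
        axis_bounds=np.column_stack([lo, hi]),
    )


# ---------------------------------------------------------------------------
# occupancy grids


def _silverman(x: np.ndarray) -> float:
    # 2-D Silverman factor: (4/(d+2))^(1/(d+4)) n^(-1/(d+4)) = n^(-1/6) at d=2
    n = len(x)
    sd = x.std(ddof=0)
    if sd == 0:
        sd = 1e-6
    return sd * n ** (-1.0 / 6.0)


def _axis_kernel(points: np.ndarray, centers: np.ndarray, h: float) -> np.ndarray:
    """(n_points, n_centers) truncated Gaussian kernel matrix for one axis."""
    u = (points[:, None] - centers[None, :]) / h
    k = np.exp(-0.5 * u * u)
    k[np.abs(u) > KERNEL_TRUNCATION] = 0.0
    return k


def _kde_grid(scores: np.ndarray, space: EnvSpace, h: tuple[float, float]) -> np.ndarray:
    """Separable truncated-Gaussian KDE evaluated on the occupancy grid."""
    xs, ys = space.grid_axes()
    kx = _axis_kernel(scores[:, 0], xs, h[0])
    ky = _axis_kernel(scores[:, 1], ys, h[1])
    dens = kx.T @ ky  # (R, R): rows = axis 1, cols = axis 2
    return dens / max(len(scores), 1)


class BackgroundFields:
    """Precomputed background KDE of one range, reusable across permutations."""

    def __init__(self, bg_scores: np.ndarray, space: EnvSpace) -> None:
        bg_scores = np.atleast_2d(np.asarray(bg_scores, float))
        h_bg = (_silverman(bg_scores[:, 0]), _silverman(bg_scores[:, 1]))
        self.density = _kde_grid(bg_scores, space, h_bg)
        self.support = self.density > 0
        self.mask = self.density > MASK_THRESHOLD * self.density.max()


def _occupancy_from_fields(
    occ_scores: np.ndarray, fields: BackgroundFields, space: EnvSpace
) -> OccupancyGrid:
    occ_scores = np.atleast_2d(np.asarray(occ_scores, float))
    if len(occ_scores) < 5:
        raise ValueError("need at least 5 occurrence scores")
    (x0, x1), (y0, y1) = space.axis_bounds
    in_bounds = (
        (occ_scores[:, 0] >= x0)
        & (occ_scores[:, 0] <= x1)
        & (occ_scores[:, 1] >= y0)
        & (occ_scores[:, 1] <= y1)
    )
    if not in_bounds.any():
        raise ValueError(
            "all occurrences fall outside the environment-space bounds; rebuild the space"
        )
    h_occ = (_silverman(occ_scores[:, 0]), _silverman(occ_scores[:, 1]))
    occ_dens = _kde_grid(occ_scores, space, h_occ)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(fields.mask, occ_dens / fields.density, 0.0)
    total = z.sum()
    if total == 0:
        raise ValueError("occurrence density vanishes on the background mask")
    z_raw = occ_dens / occ_dens.sum() if occ_dens.sum() > 0 else occ_dens
    return OccupancyGrid(
        z=z / total,
        z_raw=z_raw,
        background_mask=fields.mask,
        support_mask=fields.support,
        bg_density=fields.density,
    )


def occupancy_grid(
    occ_scores: np.ndarray,
    bg_scores: np.ndarray,
    space: EnvSpace,
) -> OccupancyGrid:
    """Availability-corrected occupancy of one range.

    The corrected occupancy is occurrence density divided by background
    density inside the background mask (zero elsewhere), renormalized to sum
    to 1.  The uncorrected density is retained for the dynamics indices and
    diagnostics.
    """
    return _occupancy_from_fields(occ_scores, BackgroundFields(bg_scores, space), space)


# ---------------------------------------------------------------------------
# overlap and permutation tests


def schoener_d(z1: OccupancyGrid | np.ndarray, z2: OccupancyGrid | np.ndarray) -> float:
    """Schoener's overlap D = 1 - 0.5 sum |z1 - z2| between occupancy surfaces."""
    a = z1.z if isinstance(z1, OccupancyGrid) else np.asarray(z1, float)
    b = z2.z if isinstance(z2, OccupancyGrid) else np.asarray(z2, float)
    if a.shape != b.shape:
        raise ValueError("occupancy grids have mismatched shapes")
    return float(1.0 - 0.5 * np.abs(a - b).sum())


def _observed_d(occ1, occ2, fields1, fields2, space):
    g1 = _occupancy_from_fields(occ1, fields1, space)
    g2 = _occupancy_from_fields(occ2, fields2, space)
    return schoener_d(g1, g2), g1, g2


def equivalency_test(
    occ1: np.ndarray,
    occ2: np.ndarray,
    bg1: np.ndarray,
    bg2: np.ndarray,
    space: EnvSpace,
    reps: int = 100,
    seed: int = 0,
    direction: str = "lower",
) -> tuple[float, np.ndarray, float]:
    """Niche-equivalency permutation test.

    Pooled occurrences are randomly re-split into the two original sample
    sizes each iteration and D recomputed.  With ``direction="lower"`` the
    p-value is (#{D_null <= D_obs} + 1) / (reps + 1): small p means the
    observed niches are less equivalent than random re-assignments.

    Returns (p, null D values, observed D).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    fields1 = BackgroundFields(bg1, space)
    fields2 = BackgroundFields(bg2, space)
    d_obs, _, _ = _observed_d(occ1, occ2, fields1, fields2, space)
    pooled = np.vstack([occ1, occ2])
    n1 = len(occ1)
    null = np.empty(reps)
    for i in range(reps):
        perm = rng.permutation(len(pooled))
        a, b = pooled[perm[:n1]], pooled[perm[n1:]]
        null[i] = schoener_d(
            _occupancy_from_fields(a, fields1, space),
            _occupancy_from_fields(b, fields2, space),
        )
    if direction == "lower":
        k = int(np.sum(null <= d_obs))
    elif direction == "upper":
        k = int(np.sum(null >= d_obs))
    else:
        raise ValueError("direction must be 'lower' or 'upper'")
    p = (k + 1) / (reps + 1)
    return p, null, d_obs


def _shift_grid(z: np.ndarray, mask: np.ndarray, target_rc: tuple[int, int]) -> np.ndarray:
    """Translate an occupancy surface so its centroid lands on target_rc.

    The translation wraps at the grid bounds; mass landing outside the
    range's background mask is zeroed and the surface renormalized.
    """
    R = z.shape[0]
    total = z.sum()
    rows = np.arange(z.shape[0])
    cols = np.arange(z.shape[1])
    cr = int(round((z.sum(axis=1) @ rows) / total))
    cc = int(round((z.sum(axis=0) @ cols) / total))
    shifted = np.roll(z, (target_rc[0] - cr, target_rc[1] - cc), axis=(0, 1))
    shifted = np.where(mask, shifted, 0.0)
    s = shifted.sum()
    return shifted / s if s > 0 else shifted


def similarity_test(
    occ1: np.ndarray,
    occ2: np.ndarray,
    bg1: np.ndarray,
    bg2: np.ndarray,
    space: EnvSpace,
    reps: int = 100,
    seed: int = 0,
    shift: str = "invaded",
) -> tuple[float, np.ndarray, float]:
    """Niche-similarity (background) permutation test.

    Each iteration relocates one range's corrected occupancy surface to a
    random cell of its background mask (centroid translation with wraparound)
    and recomputes D.  p = (#{D_null >= D_obs} + 1)/(reps + 1): small p means
    the two niches are more similar than expected from background choice.

    ``shift`` selects which range is relocated: "invaded" (default),
    "native", or "both" (each iteration shifts both, the stricter
    two-direction variant).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if shift not in {"invaded", "native", "both"}:
        raise ValueError("shift must be 'invaded', 'native' or 'both'")
    rng = np.random.default_rng(seed)
    fields1 = BackgroundFields(bg1, space)
    fields2 = BackgroundFields(bg2, space)
    d_obs, g1, g2 = _observed_d(occ1, occ2, fields1, fields2, space)
    null = np.empty(reps)
    cand1 = np.argwhere(g1.background_mask)
    cand2 = np.argwhere(g2.background_mask)
    for i in range(reps):
        z1 = g1.z
        z2 = g2.z
        if shift in {"native", "both"}:
            rc = tuple(cand1[rng.integers(len(cand1))])
            z1 = _shift_grid(g1.z, g1.background_mask, rc)
        if shift in {"invaded", "both"}:
            rc = tuple(cand2[rng.integers(len(cand2))])
            z2 = _shift_grid(g2.z, g2.background_mask, rc)
        null[i] = schoener_d(z1, z2)
    k = int(np.sum(null >= d_obs))
    p = (k + 1) / (reps + 1)
    return p, null, d_obs


# ---------------------------------------------------------------------------
# niche dynamics


def niche_dynamics(
    z_native: OccupancyGrid,
    z_invaded: OccupancyGrid,
    intersection_quantile: float = 0.0,
    use_corrected: bool = False,
) -> tuple[float, float, float]:
    """Expansion / stability / unfilling within the shared environmental envelope.

    The analysis is restricted to the intersection of the two ranges'
    environmental envelopes (cells with background density above the given
    quantile of each range's positive densities; quantile 0 keeps the full
    envelopes).  With the invaded occupancy renormalized over the
    intersection: expansion is its mass where the native occupancy is zero,
    stability the complement; unfilling is the native mass (likewise
    renormalized) where the invaded occupancy is zero.

    By default the indices are computed on the uncorrected occurrence
    densities (the availability correction is a ratio estimate that blows up
    precisely in the rare environments where expansion occurs);
    ``use_corrected`` switches to the corrected surfaces.
    """
    if z_native.z.shape != z_invaded.z.shape:
        raise ValueError("occupancy grids have mismatched shapes")
    if intersection_quantile > 0:
        masks = []
        for g in (z_native, z_invaded):
            if g.bg_density is None:
                raise ValueError("quantile trimming needs grids built with a background")
            pos = g.bg_density[g.support_mask]
            thr = np.quantile(pos, intersection_quantile)
            masks.append(g.bg_density >= thr)
        inter = masks[0] & masks[1]
    else:
        inter = z_native.support_mask & z_invaded.support_mask
    if not inter.any():
        raise ValueError("environmental envelopes do not intersect")
    zn_full = z_native.z if use_corrected else z_native.z_raw
    zi_full = z_invaded.z if use_corrected else z_invaded.z_raw
    zn = np.where(inter, zn_full, 0.0)
    zi = np.where(inter, zi_full, 0.0)
    zn_total = zn.sum()
    zi_total = zi.sum()
    if zi_total == 0 or zn_total == 0:
        raise ValueError("no occupancy mass inside the shared envelope")
    zn = zn / zn_total
    zi = zi / zi_total
    expansion = float(zi[zn == 0].sum())
    stability = float(zi[zn > 0].sum())
    unfilling = float(zn[zi == 0].sum())
    return expansion, stability, unfilling


# ---------------------------------------------------------------------------
# one-call comparison


def compare_niches(
    occ1_X: np.ndarray,
    occ2_X: np.ndarray,
    bg1_X: np.ndarray,
    bg2_X: np.ndarray,
    grid_R: int = 100,
    reps: int = 100,
    seed: int = 0,
    intersection_quantile: float = 0.0,
) -> NicheComparison:
    """Run the full COUE comparison from raw covariate matrices."""
    space = build_env_space(bg1_X, bg2_X, grid_R=grid_R)
    s_occ1 = space.scores(occ1_X)
    s_occ2 = space.scores(occ2_X)
    s_bg1 = space.scores(bg1_X)
    s_bg2 = space.scores(bg2_X)
    g1 = occupancy_grid(s_occ1, s_bg1, space)
    g2 = occupancy_grid(s_occ2, s_bg2, space)
    d = schoener_d(g1, g2)
    p_eq, null_eq, _ = equivalency_test(
        s_occ1, s_occ2, s_bg1, s_bg2, space, reps=reps, seed=seed
    )
    p_sim, null_sim, _ = similarity_test(
        s_occ1, s_occ2, s_bg1, s_bg2, space, reps=reps, seed=seed + 1
    )
    expansion, stability, unfilling = niche_dynamics(g1, g2, intersection_quantile)
    return NicheComparison(
        D=d,
        p_equivalency=p_eq,
        p_similarity=p_sim,
        expansion=expansion,
        stability=stability,
        unfilling=unfilling,
        reps=reps,
        null_equivalency=null_eq,
        null_similarity=null_sim,
    )
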