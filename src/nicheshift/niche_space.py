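"""Two-axis PCA environmental space and kernel-smoothed niche densities.

The background environment of the whole study area is ordinated by a
correlation-matrix PCA (variables z-scored first, so measurement scale is
irrelevant). The realized niche of a taxon is then the kernel-smoothed
density of its occurrences over an R x R grid spanning the first two PCA
axes, bounded by the minimum and maximum environmental conditions
available in the study area. Dividing occurrence density by the density
of available environments corrects for the uneven availability of
conditions; overlap between two taxa is Schoener's D on the normalized
grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EnvSpace",
    "DensityGrid",
    "DensityGridBuilder",
    "fit_pca_env",
    "project_scores",
    "density_grid",
    "schoener_D",
]


@dataclass
class EnvSpace:
    """A fitted 2-axis ordination of the study-area environment."""

    variables: list[str]
    means: np.ndarray            # per-variable mean used for standardization
    sds: np.ndarray              # per-variable sd used for standardization
    loadings: np.ndarray         # variables x 2, orthonormal columns
    explained_variance: np.ndarray   # top-2 eigenvalues of the correlation matrix
    explained_fraction: np.ndarray   # eigenvalues / total variance
    axis_ranges: np.ndarray      # 2 x 2: per-axis (min, max) of calibration scores

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.loadings, index=self.variables, columns=["pc1", "pc2"])
        df.loc["_eigenvalue"] = self.explained_variance
        df.loc["_explained_fraction"] = self.explained_fraction
        return df


def fit_pca_env(background_env: pd.DataFrame,
                variables: list[str] | None = None) -> EnvSpace:
    """Correlation-matrix PCA of the study-area background.

    Variables are standardized to zero mean and unit variance, the
    correlation matrix eigendecomposed, and the two leading eigenvectors
    kept. Sign convention: the largest-magnitude loading on each axis is
    made positive, so serialized spaces are reproducible.
    """
    if variables is None:
        variables = [c for c in background_env.columns
                     if c not in ("row", "col", "lon", "lat")]
    data = background_env[variables].to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 background rows for a PCA")
    means = data.mean(axis=0)
    sds = data.std(axis=0)
    nonzero = sds > 0
    if nonzero.sum() < 2:
        raise ValueError("need at least two variables with nonzero variance")
    variables = [v for v, ok in zip(variables, nonzero) if ok]
    data, means, sds = data[:, nonzero], means[nonzero], sds[nonzero]
    z = (data - means) / sds
    corr = (z.T @ z) / z.shape[0]
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    loadings = eigvecs[:, :2].copy()
    for axis in range(2):
        j = int(np.argmax(np.abs(loadings[:, axis])))
        if loadings[j, axis] < 0:
            loadings[:, axis] *= -1
    scores = z @ loadings
    axis_ranges = np.column_stack([scores.min(axis=0), scores.max(axis=0)])
    if np.any(axis_ranges[:, 1] - axis_ranges[:, 0] <= 0):
        raise ValueError("degenerate axis range: background scores have zero span")
    return EnvSpace(
        variables=variables,
        means=means,
        sds=sds,
        loadings=loadings,
        explained_variance=eigvals[:2],
        explained_fraction=eigvals[:2] / eigvals.sum(),
        axis_ranges=axis_ranges,
    )


def project_scores(space: EnvSpace, env: pd.DataFrame) -> np.ndarray:
    """Project an environment table onto the two stored PCA axes."""
    missing = [v for v in space.variables if v not in env.columns]
    if missing:
        raise KeyError(f"environment table missing variables {missing}")
    z = (env[space.variables].to_numpy(dtype=float) - space.means) / space.sds
    return z @ space.loadings


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb for a 1-D Gaussian kernel."""
    n = x.size
    sd = x.std()
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(x.mean()), 1.0) * 1e-3
    return 0.9 * spread * n ** (-0.2)


@dataclass
class DensityGrid:
    """Kernel densities of a taxon and its background in PCA space.

    ``occ_density`` and ``occ_corrected`` are max-normalized (peak = 1);
    ``occ_raw``/``env_raw`` are the unnormalized kernel density estimates
    (integrating to about 1 over the extent when the points sit well
    inside it). ``occ_corrected`` is occupancy divided by availability,
    defined as 0 where availability is zero.
    """

    R: int
    extent: np.ndarray           # 2 x 2: per-axis (min, max)
    occ_density: np.ndarray      # R x R, max-normalized
    env_density: np.ndarray      # R x R, raw availability KDE
    occ_corrected: np.ndarray    # R x R, max-normalized occupancy/availability
    occ_raw: np.ndarray
    env_raw: np.ndarray
    bandwidths: np.ndarray       # per-axis occurrence kernel bandwidths

    @property
    def cell_area(self) -> float:
        dx = (self.extent[0, 1] - self.extent[0, 0]) / self.R
        dy = (self.extent[1, 1] - self.extent[1, 0]) / self.R
        return dx * dy

    def axis_centers(self, axis: int) -> np.ndarray:
        lo, hi = self.extent[axis]
        step = (hi - lo) / self.R
        return lo + (np.arange(self.R) + 0.5) * step

    def grid(self, corrected: bool = True) -> np.ndarray:
        return self.occ_corrected if corrected else self.occ_density

    def centroid(self, corrected: bool = True) -> np.ndarray:
        """Mass-weighted centroid of the chosen density, in axis units."""
        g = self.grid(corrected)
        total = g.sum()
        if total == 0:
            raise ValueError("empty density grid has no centroid")
        x = self.axis_centers(0)
        y = self.axis_centers(1)
        return np.array([(g.sum(axis=1) @ x) / total, (g.sum(axis=0) @ y) / total])


def _separable_kde(points: np.ndarray, xc: np.ndarray, yc: np.ndarray,
                   hx: float, hy: float) -> np.ndarray:
    """Gaussian product-kernel density at the grid of (xc x yc) centers.

    Returns an (len(xc), len(yc)) array: mean over points of the product
    of the per-axis Gaussian kernels. Separability makes this a single
    matrix product per axis pair.
    """
    kx = np.exp(-0.5 * ((xc[None, :] - points[:, 0:1]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((yc[None, :] - points[:, 1:2]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    return (kx.T @ ky) / points.shape[0]


class DensityGridBuilder:
    """Precomputes the background availability density for one taxon.

    Permutation tests rebuild occurrence densities hundreds of times
    against a fixed background; factoring the availability KDE out of the
    per-replicate work keeps those loops cheap.
    """

    def __init__(self, background_scores: np.ndarray, R: int = 100,
                 extent: np.ndarray | None = None):
        bg = np.atleast_2d(np.asarray(background_scores, dtype=float))
        if bg.shape[0] < 2:
            raise ValueError("need at least 2 background scores")
        if extent is None:
            extent = np.column_stack([bg.min(axis=0), bg.max(axis=0)])
        extent = np.asarray(extent, dtype=float)
        if np.any(extent[:, 1] - extent[:, 0] <= 0):
            raise ValueError("degenerate extent: zero span on an axis")
        self.R = int(R)
        self.extent = extent
        self._xc = extent[0, 0] + (np.arange(R) + 0.5) * (extent[0, 1] - extent[0, 0]) / R
        self._yc = extent[1, 0] + (np.arange(R) + 0.5) * (extent[1, 1] - extent[1, 0]) / R
        hbx = max(_silverman_bandwidth(bg[:, 0]), (extent[0, 1] - extent[0, 0]) / R)
        hby = max(_silverman_bandwidth(bg[:, 1]), (extent[1, 1] - extent[1, 0]) / R)
        self.env_raw = _separable_kde(bg, self._xc, self._yc, hbx, hby)

    def build(self, occ_scores: np.ndarray) -> DensityGrid:
        occ = np.atleast_2d(np.asarray(occ_scores, dtype=float))
        if occ.shape[0] < 1:
            raise ValueError("need at least 1 occurrence score")
        # bandwidth floor of one grid cell avoids sub-cell kernels at small n
        hx = max(_silverman_bandwidth(occ[:, 0]),
                 (self.extent[0, 1] - self.extent[0, 0]) / self.R)
        hy = max(_silverman_bandwidth(occ[:, 1]),
                 (self.extent[1, 1] - self.extent[1, 0]) / self.R)
        occ_raw = _separable_kde(occ, self._xc, self._yc, hx, hy)
        occ_density = occ_raw / occ_raw.max() if occ_raw.max() > 0 else occ_raw
        with np.errstate(divide="ignore", invalid="ignore"):
            corrected = np.where(self.env_raw > 0, occ_raw / self.env_raw, 0.0)
        if corrected.max() > 0:
            corrected = corrected / corrected.max()
        return DensityGrid(
            R=self.R,
            extent=self.extent,
            occ_density=occ_density,
            env_density=self.env_raw / self.env_raw.max() if self.env_raw.max() > 0 else self.env_raw,
            occ_corrected=corrected,
            occ_raw=occ_raw,
            env_raw=self.env_raw,
            bandwidths=np.array([hx, hy]),
        )


def density_grid(occ_scores: np.ndarray, background_scores: np.ndarray,
                 R: int = 100, extent: np.ndarray | None = None) -> DensityGrid:
    """Build occurrence/availability densities on the R x R environmental grid.

    The extent defaults to the per-axis min/max of the background scores —
    the envelope of conditions available in the study area. Deterministic:
    no randomness is involved.
    """
    return DensityGridBuilder(background_scores, R=R, extent=extent).build(occ_scores)


def schoener_D(g1: DensityGrid | np.ndarray, g2: DensityGrid | np.ndarray,
               corrected: bool = True) -> float:
    """Schoener's D niche overlap: 1 - 0.5 * sum |p1 - p2| over grid cells.

    Each grid is normalized to sum to one first, so D is invariant to any
    positive rescaling of the inputs; D = 0 means disjoint support, D = 1
    identical normalized densities. Grids must share R and extent.
    """
    if isinstance(g1, DensityGrid) and isinstance(g2, DensityGrid):
        if g1.R != g2.R or not np.allclose(g1.extent, g2.extent):
            raise ValueError("density grids differ in R or extent")
        a, b = g1.grid(corrected), g2.grid(corrected)
    else:
        a = np.asarray(g1.grid(corrected) if isinstance(g1, DensityGrid) else g1, dtype=float)
        b = np.asarray(g2.grid(corrected) if isinstance(g2, DensityGrid) else g2, dtype=float)
        if a.shape != b.shape:
            raise ValueError("grids have different shapes")
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("cannot normalize an all-zero density grid")
    return float(1.0 - 0.5 * np.abs(a / sa - b / sb).sum())
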