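"""Synthetic climate landscapes, soil masks, era shifts and occurrences.

Every downstream stage (variable filtering, maximum-entropy fitting,
multi-era projection, niche-overlap testing) is exercised against data
generated here, where the ground truth is known by construction:

* climate layers are spatially autocorrelated Gaussian random fields
  (white noise convolved with a Gaussian kernel, then mixed across layers
  to a requested cross-correlation matrix);
* eras are additive per-layer offsets on the present-day landscape;
* the substrate constraint of gypsum-restricted plants is emulated by a
  patchy binary soil mask obtained by thresholding an independent
  autocorrelated field;
* each taxon has a known logistic suitability surface (linear + quadratic
  response to the standardized layers) from which presences are drawn,
  confined to soil patches.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .geo_io import GridGeometry, OccurrenceSet, RasterStack

__all__ = [
    "DEFAULT_LAYER_NAMES",
    "bioclim_block_correlation",
    "ScenarioConfig",
    "TrueNiche",
    "generate_layers",
    "apply_era_shift",
    "generate_soil_mask",
    "true_suitability",
    "sample_occurrences",
]

# The seven bioclimatic predictors the workflow is built around: annual mean
# temperature, temperature seasonality, min temperature of the coldest month,
# temperature annual range, annual precipitation, precipitation seasonality,
# precipitation of the driest quarter.
DEFAULT_LAYER_NAMES = ("bio1", "bio4", "bio6", "bio7", "bio12", "bio15", "bio17")


def bioclim_block_correlation(within: float = 0.7, cross: float = -0.4) -> np.ndarray:
    """Realistic cross-correlation for the seven default layers.

    Temperature-derived variables (bio1, bio4, bio6, bio7) correlate with
    each other, precipitation-derived ones (bio12, bio15, bio17) likewise,
    and the two blocks are negatively related — the structure real
    bioclimatic layers show, with all pairwise |r| kept below the 0.95
    collinearity cut. The default (0.7 within, -0.4 across) is positive
    semi-definite and puts the main temperature-vs-precipitation gradient
    on the leading ordination axis.
    """
    corr = np.eye(7)
    corr[:4, :4] = np.where(np.eye(4, dtype=bool), 1.0, within)
    corr[4:, 4:] = np.where(np.eye(3, dtype=bool), 1.0, within)
    corr[:4, 4:] = cross
    corr[4:, :4] = cross
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("requested block structure is not positive semi-definite")
    return corr


@dataclass
class TrueNiche:
    """Ground-truth suitability: logistic(b0 + x.bl + (x**2).bq) on z-scored layers."""

    taxon_id: str
    beta0: float
    beta_linear: np.ndarray
    beta_quadratic: np.ndarray

    def __post_init__(self) -> None:
        self.beta_linear = np.asarray(self.beta_linear, dtype=float)
        self.beta_quadratic = np.asarray(self.beta_quadratic, dtype=float)
        if self.beta_linear.shape != self.beta_quadratic.shape:
            raise ValueError("beta_linear and beta_quadratic lengths differ")


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study landscape.

    ``layer_cross_correlation`` is the target inter-layer correlation matrix
    (must be symmetric positive semi-definite); ``era_shifts`` maps era
    labels to per-layer additive offsets in the layers' own units;
    ``niches``/``n_occurrences`` define per-taxon ground truth. The default
    ``soil_fraction`` of 0.061 mirrors the share of gypsum outcrops in the
    kind of semi-arid study region this emulates.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    cell_size: float = 0.05
    origin: tuple[float, float] = (-5.0, 38.0)
    layer_names: tuple[str, ...] = DEFAULT_LAYER_NAMES
    autocorr_length: float = 8.0
    layer_cross_correlation: np.ndarray | None = None
    era_shifts: dict[str, np.ndarray] = field(default_factory=dict)
    niches: dict[str, TrueNiche] = field(default_factory=dict)
    n_occurrences: dict[str, int] = field(default_factory=dict)
    soil_fraction: float = 0.061
    soil_patch_scale: float = 6.0
    seed: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            n_rows=self.grid_rows,
            n_cols=self.grid_cols,
            x_min=self.origin[0],
            y_min=self.origin[1],
            cell_size=self.cell_size,
        )

    def correlation_matrix(self) -> np.ndarray:
        if self.layer_cross_correlation is None:
            return np.eye(self.n_layers)
        return np.asarray(self.layer_cross_correlation, dtype=float)

    def validate(self) -> None:
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise ValueError("grid must be at least 10x10")
        if not (0.0 < self.soil_fraction <= 1.0):
            raise ValueError("soil_fraction must be in (0, 1]")
        corr = self.correlation_matrix()
        if corr.shape != (self.n_layers, self.n_layers):
            raise ValueError(
                f"cross-correlation matrix must be {self.n_layers}x{self.n_layers}"
            )
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("cross-correlation matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-8:
            raise ValueError(
                "cross-correlation matrix is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        for era, offsets in self.era_shifts.items():
            if len(np.atleast_1d(offsets)) != self.n_layers:
                raise ValueError(f"era {era!r}: offset count != n_layers")
        for taxon, n in self.n_occurrences.items():
            if n < 1:
                raise ValueError(f"taxon {taxon!r}: n_occurrences must be >= 1")
        for taxon, niche in self.niches.items():
            if niche.beta_linear.size != self.n_layers:
                raise ValueError(f"taxon {taxon!r}: niche dimension != n_layers")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  scale: float) -> np.ndarray:
    """Standardized Gaussian random field: smoothed white noise, unit variance."""
    noise = rng.standard_normal(shape)
    if scale > 0:
        f = ndimage.gaussian_filter(noise, sigma=scale, mode="wrap")
    else:
        f = noise
    return (f - f.mean()) / f.std()


def _correlation_factor(corr: np.ndarray) -> np.ndarray:
    """A matrix A with A @ A.T = corr; handles singular (rank-deficient) targets."""
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-8:
        raise ValueError("cross-correlation matrix is not positive semi-definite")
    return eigvecs @ np.diag(np.sqrt(np.clip(eigvals, 0.0, None)))


def generate_layers(config: ScenarioConfig, seed: int | None = None) -> RasterStack:
    """Generate the present-day climate stack of a scenario.

    Independent unit-variance autocorrelated fields are mixed with a factor
    of the target correlation matrix, so the realized inter-layer Pearson
    correlations approximate ``layer_cross_correlation`` (exactly 1 for
    duplicated layers). Deterministic for a fixed seed.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    shape = (config.grid_rows, config.grid_cols)
    base = np.stack(
        [_smooth_field(rng, shape, config.autocorr_length) for _ in range(config.n_layers)]
    )
    factor = _correlation_factor(config.correlation_matrix())
    mixed = np.einsum("ij,jrc->irc", factor, base)
    stack = RasterStack(geometry=config.geometry)
    for name, layer in zip(config.layer_names, mixed):
        stack.add_layer(name, layer)
    return stack


def apply_era_shift(stack: RasterStack, offsets) -> RasterStack:
    """Return a new stack with a per-layer additive climate offset.

    ``offsets`` is a sequence aligned with the stack's layer order or a
    mapping name -> offset. Nodata cells stay nodata; geometry is shared.
    """
    if isinstance(offsets, dict):
        missing = [n for n in stack.layer_names if n not in offsets]
        if missing:
            raise ValueError(f"offsets missing for layers {missing}")
        offsets = [offsets[n] for n in stack.layer_names]
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (stack.n_layers,):
        raise ValueError(
            f"expected {stack.n_layers} offsets, got shape {offsets.shape}"
        )
    out = RasterStack(geometry=stack.geometry, nodata=stack.nodata)
    for (name, arr), off in zip(stack.layers.items(), offsets):
        out.add_layer(name, arr + off)  # NaN + off stays NaN
    return out


def generate_soil_mask(geometry: GridGeometry, soil_fraction: float,
                       patch_scale: float, seed: int) -> np.ndarray:
    """Binary patchy substrate mask covering about ``soil_fraction`` of cells.

    An independent autocorrelated field is thresholded at the quantile that
    leaves ``soil_fraction`` of cells above it, yielding spatially clustered
    "outcrop" patches of characteristic size ``patch_scale`` cells.
    """
    if not (0.0 < soil_fraction <= 1.0):
        raise ValueError("soil_fraction must be in (0, 1]")
    if soil_fraction == 1.0:
        return np.ones((geometry.n_rows, geometry.n_cols), dtype=np.int8)
    rng = np.random.default_rng(seed)
    f = _smooth_field(rng, (geometry.n_rows, geometry.n_cols), patch_scale)
    cutoff = np.quantile(f, 1.0 - soil_fraction)
    return (f > cutoff).astype(np.int8)


def true_suitability(stack: RasterStack, niche: TrueNiche) -> np.ndarray:
    """Ground-truth suitability surface in (0, 1).

    Layers are z-scored over their off-nodata cells, then
    ``logistic(beta0 + sum(bl*z) + sum(bq*z**2))`` is evaluated per cell.
    """
    if niche.beta_linear.size != stack.n_layers:
        raise ValueError(
            f"niche has {niche.beta_linear.size} terms, stack has {stack.n_layers} layers"
        )
    eta = np.full((stack.geometry.n_rows, stack.geometry.n_cols), niche.beta0)
    for (name, arr), bl, bq in zip(
        stack.layers.items(), niche.beta_linear, niche.beta_quadratic
    ):
        mu = np.nanmean(arr)
        sd = np.nanstd(arr)
        z = (arr - mu) / (sd if sd > 0 else 1.0)
        eta = eta + bl * z + bq * z**2
    return expit(eta)


def sample_occurrences(suitability: np.ndarray, soil_mask: np.ndarray | None,
                       n: int, seed: int, geometry: GridGeometry,
                       taxon_id: str = "taxon", era: str | None = None) -> OccurrenceSet:
    """Draw ``n`` presence points at cell centers, P(cell) ∝ suitability x mask.

    Sampling is without replacement, mirroring the one-record-per-pixel
    thinning applied to real occurrence data downstream. Fails explicitly
    when no cell has positive weight or ``n`` exceeds the eligible cells.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = np.array(suitability, dtype=float)
    weights[~np.isfinite(weights)] = 0.0
    if soil_mask is not None:
        weights = weights * (np.asarray(soil_mask) > 0)
    flat = weights.ravel()
    eligible = np.count_nonzero(flat > 0)
    if eligible == 0:
        raise ValueError("no cell with positive sampling weight (suitability x mask)")
    if n > eligible:
        raise ValueError(f"requested {n} occurrences but only {eligible} eligible cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat.size, size=n, replace=False, p=flat / flat.sum())
    rr, cc = np.unravel_index(idx, weights.shape)
    lon = geometry.x_min + (cc + 0.5) * geometry.cell_size
    lat = geometry.y_min + (geometry.n_rows - rr - 0.5) * geometry.cell_size
    return OccurrenceSet(taxon_id=taxon_id, points=np.column_stack([lon, lat]), era=era)
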