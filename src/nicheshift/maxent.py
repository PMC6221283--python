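"""Presence-background maximum-entropy distribution modelling.

The model estimates the Gibbs distribution over background cells that has
maximum entropy subject to (regularized) feature-expectation constraints:

    q_lambda(x) = exp(lambda . f(x)) / Z_lambda ,
    Z_lambda    = sum over background cells of exp(lambda . f(x)),

fitted by maximizing the L1-penalized log-likelihood of the presences

    L(lambda) = mean_presence[ lambda . f(x) ] - log Z_lambda
                - sum_j beta_j |lambda_j| .

Only linear, quadratic and product feature classes are available; hinge
and threshold features are excluded by construction, which keeps response
curves smooth and interpretable. The per-feature penalty is

    beta_j = reg_multiplier * class_default(m) * s_j / sqrt(m)

with ``m`` the presence count, ``s_j`` the feature's standard deviation
over the presences, and ``class_default`` the published per-class
regularization tables (interpolated in ``m``). Optimization is proximal
gradient descent with backtracking, which handles the L1 term exactly and
yields a monotone objective trajectory.

Outputs: ``raw`` (the Gibbs density, summing to 1 over the training
background), ``cloglog`` (default; ``1 - exp(-exp(H) * raw)`` with ``H``
the entropy of the raw training distribution) and ``logistic``
(``exp(H)*raw / (1 + exp(H)*raw)``). Both transforms are strictly
monotone in ``raw``, so rank-based evaluation (AUC) is unaffected by the
choice.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score, roc_curve

from .geo_io import OccurrenceSet, RasterStack

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "MaxEntModel",
    "EvalReport",
    "VariableSelection",
    "select_variables",
    "make_features",
    "sample_background",
    "split_occurrences",
    "fit_maxent",
    "evaluate",
    "apply_soil_mask",
]

FEATURE_CLASSES = ("linear", "quadratic", "product")

# Published per-class regularization defaults, interpolated in the presence
# count (linear-quadratic-product configuration of the reference MaxEnt
# implementation).
_REG_TABLE = {
    "linear": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "product": ([0, 10, 17, 30, 100], [2.6, 1.6, 0.9, 0.55, 0.05]),
}


def _class_default_beta(feature_class: str, m: int) -> float:
    xs, ys = _REG_TABLE[feature_class]
    return float(np.interp(m, xs, ys))


@dataclass
class FeatureSpec:
    """Feature configuration: active classes plus per-variable scaling bounds.

    Bounds are the training min/max of each variable; values are min-max
    scaled to [0, 1] and, when clamping is on, values outside the training
    range are pinned to the bounds before feature expansion.
    """

    variables: list[str]
    classes: tuple[str, ...] = FEATURE_CLASSES
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [c for c in self.classes if c not in FEATURE_CLASSES]
        if bad:
            raise ValueError(
                f"unsupported feature classes {bad}; available: {FEATURE_CLASSES}"
            )

    @classmethod
    def from_data(cls, env: pd.DataFrame, variables: list[str] | None = None,
                  classes: tuple[str, ...] = FEATURE_CLASSES) -> "FeatureSpec":
        if variables is None:
            variables = list(env.columns)
        bounds = {
            v: (float(np.nanmin(env[v])), float(np.nanmax(env[v]))) for v in variables
        }
        return cls(variables=list(variables), classes=classes, bounds=bounds)

    def feature_names(self) -> list[str]:
        names: list[str] = []
        if "linear" in self.classes:
            names += list(self.variables)
        if "quadratic" in self.classes:
            names += [f"{v}^2" for v in self.variables]
        if "product" in self.classes:
            names += [f"{a}*{b}" for a, b in itertools.combinations(self.variables, 2)]
        return names

    def feature_class_of(self, name: str) -> str:
        if "^2" in name:
            return "quadratic"
        if "*" in name:
            return "product"
        return "linear"


def make_features(env: pd.DataFrame, spec: FeatureSpec, clamp: bool = True) -> np.ndarray:
    """Expand an environment table into the scaled feature matrix.

    Columns: scaled linear terms, their squares, and pairwise products
    (``d + d + d(d-1)/2`` columns for ``d`` variables), each in [0, 1] by
    construction. A variable with degenerate bounds scales to the constant
    0 (its features are neutralized during fitting).
    """
    missing = [v for v in spec.variables if v not in env.columns]
    if missing:
        raise KeyError(f"environment table missing variables {missing}")
    scaled = {}
    for v in spec.variables:
        lo, hi = spec.bounds[v]
        x = np.asarray(env[v], dtype=float)
        if clamp:
            x = np.clip(x, lo, hi)
        span = hi - lo
        scaled[v] = (x - lo) / span if span > 0 else np.zeros_like(x)
    cols = []
    if "linear" in spec.classes:
        cols += [scaled[v] for v in spec.variables]
    if "quadratic" in spec.classes:
        cols += [scaled[v] ** 2 for v in spec.variables]
    if "product" in spec.classes:
        cols += [scaled[a] * scaled[b] for a, b in itertools.combinations(spec.variables, 2)]
    return np.column_stack(cols)


@dataclass
class VariableSelection:
    """Outcome of the collinearity filter and the sample-size guard."""

    kept: list[str]
    dropped: list[tuple[str, str, float]]
    guard_ok: bool
    r_threshold: float


def select_variables(stack: RasterStack, r_threshold: float = 0.95,
                     n_occurrences: int | None = None) -> VariableSelection:
    """Drop collinear layers until every kept pair has |r| below threshold.

    Pairwise Pearson correlations are computed over all off-nodata cells.
    While any pair violates the threshold, the member of the worst pair
    with the larger mean absolute correlation to all other kept layers is
    dropped (its partner and r are recorded). ``guard_ok`` reports the
    over-parameterization guard: the occurrence count should be at least
    ten times the number of kept variables.
    """
    names = stack.layer_names
    if len(names) < 2:
        raise ValueError("need at least two layers to filter")
    valid = stack.valid_mask()
    data = np.column_stack([stack.layers[n][valid] for n in names])
    sds = data.std(axis=0)
    if np.all(sds == 0):
        raise ValueError("all layers are constant; correlations undefined")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = np.nan_to_num(corr, nan=1.0)  # constant layers: treat as degenerate
    kept = list(range(len(names)))
    dropped: list[tuple[str, str, float]] = []
    while True:
        worst, worst_r = None, r_threshold
        for a, b in itertools.combinations(kept, 2):
            if abs(corr[a, b]) >= worst_r:
                worst, worst_r = (a, b), abs(corr[a, b])
        if worst is None:
            break
        a, b = worst
        others_a = [abs(corr[a, k]) for k in kept if k != a]
        others_b = [abs(corr[b, k]) for k in kept if k != b]
        victim, partner = (a, b) if np.mean(others_a) >= np.mean(others_b) else (b, a)
        dropped.append((names[victim], names[partner], float(corr[victim, partner])))
        kept.remove(victim)
        if len(kept) < 2:
            break
    kept_names = [names[k] for k in kept]
    guard_ok = True
    if n_occurrences is not None:
        guard_ok = n_occurrences >= 10 * len(kept_names)
    return VariableSelection(
        kept=kept_names, dropped=dropped, guard_ok=guard_ok, r_threshold=r_threshold
    )


def sample_background(stack: RasterStack, n: int = 10000, seed: int = 0,
                      mask: np.ndarray | None = None) -> pd.DataFrame:
    """Uniform sample of distinct off-nodata cell centers with layer values.

    When fewer than ``n`` eligible cells exist, all of them are returned
    (logged). ``mask`` restricts eligibility to its nonzero cells.
    """
    valid = stack.valid_mask()
    if mask is not None:
        valid &= np.asarray(mask) > 0
    table = stack.to_table(mask=valid)
    if table.empty:
        raise ValueError("no eligible background cells")
    if len(table) <= n:
        if len(table) < n:
            logger.info("background: only %d eligible cells (requested %d); using all",
                        len(table), n)
        return table.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n, replace=False)
    return table.iloc[np.sort(idx)].reset_index(drop=True)


def split_occurrences(occ: OccurrenceSet, train_fraction: float = 0.7,
                      seed: int = 0) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Seeded shuffle-split into train/test of sizes round(f*n) and the rest."""
    n = len(occ)
    if n < 2:
        raise ValueError("need at least two occurrence records to split")
    n_train = int(np.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    return (
        OccurrenceSet(occ.taxon_id, occ.points[train_idx], era=occ.era),
        OccurrenceSet(occ.taxon_id, occ.points[test_idx], era=occ.era),
    )


@dataclass
class MaxEntModel:
    """A fitted maximum-entropy model, projectable onto any aligned stack."""

    spec: FeatureSpec
    coefficients: np.ndarray
    log_partition: float        # log Z over the training background
    entropy: float              # entropy H of the raw training distribution
    reg_multiplier: float
    output_transform: str = "cloglog"
    objective_path: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0

    @property
    def feature_names(self) -> list[str]:
        return self.spec.feature_names()

    def linear_predictor(self, env: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        return make_features(env, self.spec, clamp=clamp) @ self.coefficients

    def predict(self, env: pd.DataFrame, transform: str | None = None,
                clamp: bool = True) -> np.ndarray:
        """Suitability for each row of an environment table."""
        transform = transform or self.output_transform
        raw = np.exp(self.linear_predictor(env, clamp=clamp) - self.log_partition)
        if transform == "raw":
            return raw
        scaled = np.exp(self.entropy) * raw
        if transform == "cloglog":
            return 1.0 - np.exp(-scaled)
        if transform == "logistic":
            return scaled / (1.0 + scaled)
        raise ValueError(f"unknown output transform {transform!r}")

    def predict_stack(self, stack: RasterStack, transform: str | None = None,
                      clamp: bool = True) -> np.ndarray:
        """Project onto an aligned raster stack; nodata cells stay NaN."""
        table = stack.to_table()
        values = self.predict(table, transform=transform, clamp=clamp)
        out = np.full((stack.geometry.n_rows, stack.geometry.n_cols), np.nan)
        out[table["row"].to_numpy(), table["col"].to_numpy()] = values
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# nicheshift maxent model\n")
            fh.write(f"transform {self.output_transform}\n")
            fh.write(f"reg_multiplier {self.reg_multiplier!r}\n")
            fh.write(f"log_partition {self.log_partition!r}\n")
            fh.write(f"entropy {self.entropy!r}\n")
            fh.write(f"classes {','.join(self.spec.classes)}\n")
            fh.write(f"variables {','.join(self.spec.variables)}\n")
            for v in self.spec.variables:
                lo, hi = self.spec.bounds[v]
                fh.write(f"bound {v} {float(lo)!r} {float(hi)!r}\n")
            for name, coef in zip(self.feature_names, self.coefficients):
                fh.write(f"coef {name} {float(coef)!r}\n")

    @classmethod
    def load(cls, path) -> "MaxEntModel":
        meta: dict[str, str] = {}
        bounds: dict[str, tuple[float, float]] = {}
        coefs: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.split()
                if parts[0] == "bound":
                    bounds[parts[1]] = (float(parts[2]), float(parts[3]))
                elif parts[0] == "coef":
                    coefs[parts[1]] = float(parts[2])
                else:
                    meta[parts[0]] = parts[1]
        spec = FeatureSpec(
            variables=meta["variables"].split(","),
            classes=tuple(meta["classes"].split(",")),
            bounds=bounds,
        )
        coefficients = np.array([coefs[n] for n in spec.feature_names()])
        return cls(
            spec=spec,
            coefficients=coefficients,
            log_partition=float(meta["log_partition"]),
            entropy=float(meta["entropy"]),
            reg_multiplier=float(meta["reg_multiplier"]),
            output_transform=meta["transform"],
        )


class ConvergenceError(RuntimeError):
    """Raised when the optimizer fails to converge; carries diagnostics."""

    def __init__(self, message: str, objective_path: np.ndarray):
        super().__init__(message)
        self.objective_path = objective_path


def _penalized_objective(lam, f_pres_mean, f_bg, betas):
    logz = logsumexp(f_bg @ lam)
    return float(lam @ f_pres_mean - logz - betas @ np.abs(lam))


def fit_maxent(presence_env: pd.DataFrame, background_env: pd.DataFrame,
               spec: FeatureSpec | None = None, reg_multiplier: float = 1.0,
               max_iter: int = 5000, tol: float = 1e-6,
               output_transform: str = "cloglog") -> MaxEntModel:
    """Fit the L1-regularized maximum-entropy model.

    ``presence_env`` and ``background_env`` are tables of raw variable
    values (rows = presence records / background cells). When ``spec`` is
    omitted, a linear+quadratic+product spec with bounds from the pooled
    data is built. Raises :class:`ConvergenceError` when the penalized
    objective has not stabilized within ``max_iter`` iterations.
    """
    if len(presence_env) < 2:
        raise ValueError("need at least two presence records")
    if spec is None:
        variables = [c for c in background_env.columns
                     if c not in ("row", "col", "lon", "lat")]
        pooled = pd.concat([presence_env[variables], background_env[variables]],
                           ignore_index=True)
        spec = FeatureSpec.from_data(pooled, variables)

    f_pres = make_features(presence_env, spec)
    f_bg = make_features(background_env, spec)
    m, k = f_pres.shape
    f_pres_mean = f_pres.mean(axis=0)

    names = spec.feature_names()
    s = f_pres.std(axis=0)
    # neutralize features constant over both presences and background
    frozen = (f_pres.std(axis=0) == 0) & (f_bg.std(axis=0) == 0)
    s = np.maximum(s, 1e-3)  # floor avoids an unpenalized separating feature
    betas = np.array([
        reg_multiplier * _class_default_beta(spec.feature_class_of(nm), m) * s[j] / np.sqrt(m)
        for j, nm in enumerate(names)
    ])

    lam = np.zeros(k)
    step = 1.0
    obj = _penalized_objective(lam, f_pres_mean, f_bg, betas)
    path = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = f_bg @ lam
        w = np.exp(eta - logsumexp(eta))
        grad = f_pres_mean - f_bg.T @ w  # gradient of the smooth part
        # proximal gradient ascent with backtracking on the penalized objective
        while True:
            cand = lam + step * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * betas, 0.0)
            cand[frozen] = 0.0
            new_obj = _penalized_objective(cand, f_pres_mean, f_bg, betas)
            if new_obj >= obj - 1e-12 or step < 1e-12:
                break
            step *= 0.5
        if new_obj < obj:
            break  # no ascent possible at the minimum step: stationary
        delta = new_obj - obj
        lam, obj = cand, new_obj
        path.append(obj)
        step *= 1.3  # cautious step growth
        if delta < tol:
            converged = True
            break
    if not converged and it >= max_iter:
        raise ConvergenceError(
            f"maxent did not converge in {max_iter} iterations "
            f"(last objective change {path[-1] - path[-2]:.3g})",
            np.array(path),
        )
    log_partition = float(logsumexp(f_bg @ lam))
    raw_bg = np.exp(f_bg @ lam - log_partition)
    entropy = float(-np.sum(raw_bg * np.log(np.maximum(raw_bg, 1e-300))))
    return MaxEntModel(
        spec=spec,
        coefficients=lam,
        log_partition=log_partition,
        entropy=entropy,
        reg_multiplier=reg_multiplier,
        output_transform=output_transform,
        objective_path=np.array(path),
        converged=True,
        n_iter=it,
    )


@dataclass
class EvalReport:
    """Discrimination metrics of a fitted model on held-out presences."""

    auc: float
    tss: float
    threshold: float
    sensitivity: float
    specificity: float
    n_train: int
    n_test: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "tss": self.tss, "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "n_train": self.n_train, "n_test": self.n_test,
            "degenerate": self.degenerate,
        }


def evaluate(model: MaxEntModel | None, test_presence_env: pd.DataFrame,
             background_env: pd.DataFrame, n_train: int = 0,
             presence_scores: np.ndarray | None = None,
             background_scores: np.ndarray | None = None) -> EvalReport:
    """AUC and TSS of a model against background pseudo-absences.

    AUC is the Mann-Whitney probability that a random presence outscores a
    random background point (ties count one half), equal to the
    trapezoidal area under the ROC curve. TSS = sensitivity + specificity
    - 1 is reported at the threshold maximizing their sum. Background
    points stand in for absences, the standard presence-background
    approximation. Scores may be supplied directly (``presence_scores`` /
    ``background_scores``) to evaluate precomputed predictions.
    """
    if presence_scores is None:
        presence_scores = model.predict(test_presence_env)
    if background_scores is None:
        background_scores = model.predict(background_env)
    presence_scores = np.asarray(presence_scores, dtype=float)
    background_scores = np.asarray(background_scores, dtype=float)
    if presence_scores.size < 1 or background_scores.size < 2:
        raise ValueError("need >=1 test presence and >=2 background points")
    y = np.concatenate([np.ones(presence_scores.size), np.zeros(background_scores.size)])
    scores = np.concatenate([presence_scores, background_scores])
    if np.ptp(scores) == 0:
        return EvalReport(auc=0.5, tss=0.0, threshold=0.5, sensitivity=0.5,
                          specificity=0.5, n_train=n_train,
                          n_test=presence_scores.size, degenerate=True)
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thresholds = roc_curve(y, scores)
    youden = tpr - fpr
    best = int(np.argmax(youden))
    threshold = float(min(max(thresholds[best], 0.0), 1.0))
    return EvalReport(
        auc=auc,
        tss=float(youden[best]),
        threshold=threshold,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        n_train=n_train,
        n_test=presence_scores.size,
    )


def apply_soil_mask(suitability: np.ndarray, soil: np.ndarray) -> np.ndarray:
    """Zero the suitability surface outside the substrate mask.

    Emulates the hard edaphic constraint of substrate-restricted plants:
    whatever the climate says, suitability is zero off the soil patches.
    NaN (nodata) cells remain NaN.
    """
    suitability = np.asarray(suitability, dtype=float)
    soil = np.asarray(soil)
    if soil.shape != suitability.shape:
        raise ValueError(
            f"soil mask shape {soil.shape} != suitability shape {suitability.shape}"
        )
    return np.where(soil > 0, suitability, np.where(np.isnan(suitability), np.nan, 0.0))
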