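"""Presence-only ecological niche modelling and niche-overlap statistics.

The model is a minimal maximum-entropy (Gibbs) density over background
grid cells: ``q(cell) ∝ exp(sum_j lambda_j f_j(cell))`` with linear and
quadratic features of each environmental layer scaled to [0, 1] over the
background. Coefficients are fit by minimizing the L1-regularized
presence log-loss, a smooth convex problem solved deterministically with
L-BFGS-B on a positive/negative split of each coefficient. The module
also provides layer screening (Spearman correlations, PCA), response
curves without extrapolation, jackknife variable importance, rank-based
AUC, a sampling-location-restricted null-model significance test, and
Schoener's D niche overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata, spearmanr
from sklearn.decomposition import PCA

from .errors import InputError, NumericalError

__all__ = [
    "EnvGrid",
    "OccurrenceSet",
    "SuitabilitySurface",
    "OverlapResult",
    "NullModelResult",
    "spearman_matrix",
    "layer_pca",
    "fit_maxent",
    "response_curve",
    "variable_importance",
    "auc",
    "null_model_test",
    "schoener_d",
]


@dataclass
class EnvGrid:
    """Named stack of co-registered raster layers.

    Cell-center registration; row 0 is the northernmost row; the mask is
    True on ocean (valid) cells.
    """

    layers: dict[str, np.ndarray]
    mask: np.ndarray  # True = ocean
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.layers.values()} | {self.mask.shape}
        if len(shapes) != 1:
            raise InputError("all layers and the mask must share one shape")
        for name, v in self.layers.items():
            if not np.all(np.isfinite(v[self.mask])):
                raise InputError(f"layer {name!r} has non-finite ocean values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def ocean_table(self) -> pd.DataFrame:
        """Ocean-cell values, one column per layer, row order = flat mask order."""
        return pd.DataFrame({k: v[self.mask] for k, v in self.layers.items()})

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        nrows = self.shape[0]
        lon = self.xll + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.yll + (nrows - np.asarray(row) - 0.5) * self.cellsize
        return lon, lat

    def snap(self, lon: np.ndarray, lat: np.ndarray):
        """(row, col) of the cells containing the given coordinates."""
        nrows, ncols = self.shape
        col = np.floor((np.asarray(lon) - self.xll) / self.cellsize).astype(int)
        row = nrows - 1 - np.floor((np.asarray(lat) - self.yll) / self.cellsize).astype(int)
        if np.any((row < 0) | (row >= nrows) | (col < 0) | (col >= ncols)):
            raise InputError("occurrence coordinates fall outside the grid")
        return row, col


@dataclass
class OccurrenceSet:
    """Georeferenced presence records for one morphotype."""

    lon: np.ndarray
    lat: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.lon = np.atleast_1d(np.asarray(self.lon, float))
        self.lat = np.atleast_1d(np.asarray(self.lat, float))
        if self.lon.shape != self.lat.shape:
            raise InputError("lon and lat must have equal length")

    def __len__(self) -> int:
        return len(self.lon)


@dataclass
class SuitabilitySurface:
    """Normalized per-cell suitability with the fitted coefficients."""

    values: np.ndarray  # full grid, NaN off-ocean, sums to 1 over ocean
    grid: EnvGrid
    lambdas: np.ndarray
    feature_names: list[str]
    feature_kinds: list[str]  # "linear" | "quadratic" per feature
    scale_min: dict[str, float]
    scale_max: dict[str, float]
    background_mean: dict[str, float]  # scaled-units mean per layer
    presence_rows: np.ndarray | None = None
    presence_cols: np.ndarray | None = None

    @property
    def ocean_values(self) -> np.ndarray:
        return self.values[self.grid.mask]


@dataclass
class OverlapResult:
    D: float
    pair: tuple[str, str] = ("", "")


@dataclass
class NullModelResult:
    observed_auc: float
    null_aucs: np.ndarray
    p: float
    seed: int | None = None


# ---------------------------------------------------------------------------
# layer screening


def spearman_matrix(grid: EnvGrid, cells: np.ndarray | None = None) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between layers over ocean cells."""
    table = grid.ocean_table()
    if cells is not None:
        table = table.iloc[cells]
    if table.shape[1] < 2:
        raise InputError("need at least 2 layers")
    const = [c for c in table.columns if table[c].nunique() <= 1]
    if const:
        warnings.warn(f"constant layers give undefined rho: {const}", stacklevel=2)
    rho = spearmanr(table.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-layer case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    out = pd.DataFrame(rho, index=table.columns, columns=table.columns)
    for c in const:
        out.loc[c, :] = np.nan
        out.loc[:, c] = np.nan
    np.fill_diagonal(out.values, 1.0)
    return out


def layer_pca(grid: EnvGrid) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of z-scored ocean-cell layer values.

    Returns (loadings, variance_fractions); variable selection from the
    report is left to the user.
    """
    table = grid.ocean_table()
    if table.shape[1] < 2:
        raise InputError("need at least 2 layers")
    X = table.to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        warnings.warn("constant layer in PCA input", stacklevel=2)
        sd = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA()
    pca.fit(Z)
    loadings = pd.DataFrame(
        pca.components_,
        columns=table.columns,
        index=[f"PC{i+1}" for i in range(pca.n_components_)],
    )
    return loadings, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# maxent fit


def _build_features(
    grid: EnvGrid,
    features: tuple[str, ...],
    scale_min: dict | None = None,
    scale_max: dict | None = None,
):
    """Feature matrix over ocean cells; layers scaled to [0,1] on background."""
    bad = set(features) - {"linear", "quadratic"}
    if bad:
        raise InputError(f"unsupported feature kinds: {sorted(bad)}")
    table = grid.ocean_table()
    if scale_min is None:
        scale_min = {c: float(table[c].min()) for c in table.columns}
        scale_max = {c: float(table[c].max()) for c in table.columns}
    cols, names, kinds = [], [], []
    for c in table.columns:
        rng = scale_max[c] - scale_min[c]
        s = (table[c].to_numpy() - scale_min[c]) / (rng if rng else 1.0)
        if "linear" in features:
            cols.append(s)
            names.append(c)
            kinds.append("linear")
        if "quadratic" in features:
            cols.append(s**2)
            names.append(c)
            kinds.append("quadratic")
    F = np.column_stack(cols)
    return F, names, kinds, scale_min, scale_max


def _fit_lambdas(F: np.ndarray, presence_ix: np.ndarray, beta: np.ndarray):
    """Minimize the L1-regularized presence log-loss of the Gibbs density.

    With no penalty the problem is smooth and solved directly; with L1
    penalties each coefficient is split into positive and negative parts
    so the objective stays differentiable on the feasible orthant.
    """
    k = F.shape[1]
    f_bar = F[presence_ix].mean(axis=0)
    opts = {"gtol": 1e-8, "ftol": 1e-14, "maxiter": 10000, "maxcor": 30, "maxls": 60}

    def _nll_grad(lam):
        logits = F @ lam
        lse = logsumexp(logits)
        w = np.exp(logits - lse)
        return lse - f_bar @ lam, w @ F - f_bar

    if np.all(beta == 0.0):
        res = minimize(_nll_grad, np.zeros(k), jac=True,
                       method="L-BFGS-B", options=opts)
        if not res.success and res.status != 1:
            raise NumericalError(f"maxent optimization failed: {res.message}")
        return res.x

    def objective(z):
        nll, grad_lam = _nll_grad(z[:k] - z[k:])
        return nll + beta @ (z[:k] + z[k:]), np.concatenate(
            [grad_lam + beta, -grad_lam + beta]
        )

    # warm start from the unpenalized solution, split by sign
    res0 = minimize(_nll_grad, np.zeros(k), jac=True,
                    method="L-BFGS-B", options=opts)
    z0 = np.concatenate([np.clip(res0.x, 0, None), np.clip(-res0.x, 0, None)])
    res = minimize(objective, z0, jac=True, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * k), options=opts)
    if not res.success and res.status != 1:
        raise NumericalError(f"maxent optimization failed: {res.message}")
    return res.x[:k] - res.x[k:]


def _presence_cells(occ: OccurrenceSet, grid: EnvGrid, dedupe: bool):
    row, col = grid.snap(occ.lon, occ.lat)
    if not np.all(grid.mask[row, col]):
        raise InputError("some occurrences fall on masked (land) cells")
    if dedupe:
        uniq = np.unique(np.column_stack([row, col]), axis=0)
        row, col = uniq[:, 0], uniq[:, 1]
    return row, col


def fit_maxent(
    occ: OccurrenceSet,
    grid: EnvGrid,
    features: tuple[str, ...] = ("linear", "quadratic"),
    beta: float | None = None,
    dedupe: bool = True,
) -> SuitabilitySurface:
    """Fit the maximum-entropy suitability surface for one morphotype.

    ``beta`` is the L1 penalty per feature; the default scales as
    ``0.05 / sqrt(m)`` with m the number of presence cells, so the
    penalty vanishes as presences accumulate. ``beta=0`` gives the pure
    moment-matching maxent solution.
    """
    row, col = _presence_cells(occ, grid, dedupe)
    m = len(row)
    if m < 5:
        raise InputError("need at least 5 presence cells")
    F, names, kinds, smin, smax = _build_features(grid, features)
    n_base = len(grid.layer_names)
    if m < n_base:
        raise InputError(
            "fewer presences than environmental variables; use linear-only features"
        )
    if beta is None:
        beta = 0.05 / np.sqrt(m)
    beta_vec = np.full(F.shape[1], float(beta))

    # flat index of presences within the ocean-cell ordering
    flat_ocean = np.flatnonzero(grid.mask.ravel())
    flat_pres = row * grid.shape[1] + col
    presence_ix = np.searchsorted(flat_ocean, flat_pres)

    lam = _fit_lambdas(F, presence_ix, beta_vec)
    logits = F @ lam
    q = np.exp(logits - logsumexp(logits))
    values = np.full(grid.shape, np.nan)
    values[grid.mask] = q
    bg_mean = {c: float(np.mean((grid.ocean_table()[c] - smin[c]) /
                                ((smax[c] - smin[c]) or 1.0))) for c in grid.layer_names}
    return SuitabilitySurface(
        values=values, grid=grid, lambdas=lam, feature_names=names,
        feature_kinds=kinds, scale_min=smin, scale_max=smax,
        background_mean=bg_mean, presence_rows=row, presence_cols=col,
    )


def _loglik(surface: SuitabilitySurface) -> float:
    """Mean presence log-density of a fitted surface."""
    q = surface.values[surface.presence_rows, surface.presence_cols]
    return float(np.mean(np.log(q)))


def response_curve(
    model: SuitabilitySurface, variable: str, n_points: int = 100
) -> pd.DataFrame:
    """Marginal response along one variable, clamped to its observed range.

    Other variables are held at their background means; queries outside
    the background range of ``variable`` are clamped to the endpoints
    (no extrapolation). The response is the relative suitability scaled
    to a maximum of 1.
    """
    if variable not in model.grid.layer_names:
        raise InputError(f"unknown variable {variable!r}")
    lo, hi = model.scale_min[variable], model.scale_max[variable]
    values = np.linspace(lo, hi, n_points)
    resp = np.array([_point_score(model, variable, v) for v in values])
    if resp.max() > 0:
        resp = resp / resp.max()
    return pd.DataFrame({"value": values, "response": resp})


def _point_score(model: SuitabilitySurface, variable: str, value: float) -> float:
    rng = model.scale_max[variable] - model.scale_min[variable]
    s_var = (value - model.scale_min[variable]) / (rng if rng else 1.0)
    s_var = min(max(s_var, 0.0), 1.0)  # clamp: no extrapolation
    logit = 0.0
    for lam, name, kind in zip(model.lambdas, model.feature_names, model.feature_kinds):
        s = s_var if name == variable else model.background_mean[name]
        logit += lam * (s if kind == "linear" else s**2)
    return float(np.exp(logit))


def evaluate_at(model: SuitabilitySurface, variable: str, value: float) -> float:
    """Clamped single-point response (same contract as response_curve)."""
    return _point_score(model, variable, value)


def variable_importance(
    model: SuitabilitySurface,
    occ: OccurrenceSet,
    grid: EnvGrid,
    beta: float | None = None,
) -> pd.Series:
    """Jackknife percent contribution per environmental variable.

    The importance of a variable is the drop in mean presence
    log-likelihood when the model is refit without it, normalized so the
    contributions sum to 100. This is a deterministic leave-one-variable-
    out gain, not the path-dependent heuristic of other maxent software.
    """
    names = grid.layer_names
    if len(names) < 2:
        return pd.Series({names[0]: 100.0}, name="percent_contribution")
    kinds = tuple(dict.fromkeys(model.feature_kinds))
    full_ll = _loglik(model)
    # refit on exactly the presence cells the full model was trained on,
    # so full and reduced likelihoods weight presences identically
    lon, lat = grid.cell_center(model.presence_rows, model.presence_cols)
    occ_fit = OccurrenceSet(lon=lon, lat=lat, label=occ.label)
    drops = {}
    for v in names:
        reduced = EnvGrid(
            layers={k: grid.layers[k] for k in names if k != v},
            mask=grid.mask, xll=grid.xll, yll=grid.yll,
            cellsize=grid.cellsize, nodata=grid.nodata,
        )
        refit = fit_maxent(occ_fit, reduced, features=kinds, beta=beta, dedupe=False)
        drops[v] = max(full_ll - _loglik(refit), 0.0)
    total = sum(drops.values())
    if total == 0.0:
        contrib = {v: 100.0 / len(names) for v in names}
    else:
        contrib = {v: 100.0 * d / total for v, d in drops.items()}
    return pd.Series(contrib, name="percent_contribution")


# ---------------------------------------------------------------------------
# evaluation


def auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank-based presence-vs-background AUC (Mann-Whitney, midrank ties)."""
    sp = np.asarray(scores_presence, float)
    sb = np.asarray(scores_background, float)
    if len(sp) < 1 or len(sb) < 1:
        raise InputError("need at least one presence and one background score")
    ranks = rankdata(np.concatenate([sp, sb]))
    m = len(sp)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * len(sb)))


def surface_auc(model: SuitabilitySurface) -> float:
    """Training AUC of a fitted surface against all background cells."""
    pres = model.values[model.presence_rows, model.presence_cols]
    return auc(pres, model.ocean_values)


def null_model_test(
    occ: OccurrenceSet,
    grid: EnvGrid,
    sampling_locations: OccurrenceSet,
    n_rand: int = 99,
    seed: int | None = None,
    features: tuple[str, ...] = ("linear", "quadratic"),
    beta: float | None = None,
) -> NullModelResult:
    """Presence-only null-model significance test of a niche model.

    The observed model's training AUC is ranked against AUCs of models
    refit on random draws of ``len(occ)`` points from the known sampling
    locations (which corrects for collection bias); the upper-tail p has
    resolution ``1/(n_rand+1)``.
    """
    if len(sampling_locations) < len(occ):
        raise InputError("need at least as many sampling locations as occurrences")
    obs_model = fit_maxent(occ, grid, features=features, beta=beta)
    obs_auc = surface_auc(obs_model)
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(n_rand)
    for r in range(n_rand):
        ix = rng.choice(len(sampling_locations), size=len(occ), replace=False)
        rand_occ = OccurrenceSet(
            lon=sampling_locations.lon[ix], lat=sampling_locations.lat[ix],
            label=f"null_{r}",
        )
        null_aucs[r] = surface_auc(fit_maxent(rand_occ, grid, features=features, beta=beta))
    p = float((1 + np.sum(null_aucs >= obs_auc)) / (n_rand + 1))
    return NullModelResult(observed_auc=obs_auc, null_aucs=null_aucs, p=p, seed=seed)


def schoener_d(s1: SuitabilitySurface, s2: SuitabilitySurface) -> OverlapResult:
    """Schoener's D overlap between two suitability surfaces.

    Both surfaces are renormalized to sum to 1 over the shared ocean
    cells; ``D = 1 - 0.5 * sum |p1 - p2|`` is 1 for identical niches and
    0 for disjoint ones.
    """
    if s1.grid.shape != s2.grid.shape or not np.array_equal(s1.grid.mask, s2.grid.mask):
        raise InputError("surfaces must share one grid and mask")
    p1 = s1.ocean_values.astype(float)
    p2 = s2.ocean_values.astype(float)
    if p1.sum() <= 0 or p2.sum() <= 0:
        raise InputError("surfaces must have positive total suitability")
    p1 = p1 / p1.sum()
    p2 = p2 / p2.sum()
    d = 1.0 - 0.5 * float(np.abs(p1 - p2).sum())
    return OverlapResult(D=d)
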