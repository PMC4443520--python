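"""Shell-shape analysis from digitized outlines.

The stage mirrors the standard outline-based geometric-morphometrics
workflow for shells that lack true landmarks: an outline is resampled to
equally spaced semi-landmarks, configurations are superimposed by
generalized least-squares Procrustes analysis (GPA), shape variation is
summarized by relative warps (principal components of the aligned
coordinates), repeatability of each warp is screened with intraclass
correlation coefficients from duplicate digitizations, and group
structure is assessed with linear discriminant assignment (jackknifed
confusion matrix) and distance-based permutational MANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .errors import InputError, NumericalError

__all__ = [
    "Outline",
    "LandmarkConfiguration",
    "ProcrustesResult",
    "RWResult",
    "RepeatabilityReport",
    "PermanovaResult",
    "ConfusionMatrix",
    "resample_outline",
    "centroid_size",
    "gpa",
    "relative_warps",
    "icc",
    "select_repeatable",
    "lda_fit_assign",
    "jackknife_confusion",
    "permanova",
    "sequential_bonferroni",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Outline:
    """An ordered planar contour of a shell.

    Ventral outlines are open curves running from one aperture-edge
    anchor around the septum to the other anchor; apertural outlines are
    closed curves starting at a single anchor.
    """

    points: np.ndarray  # (n, 2)
    is_closed: bool = False
    anchor_indices: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InputError("outline points must be an (n, 2) array")
        if len(self.points) < 3:
            raise InputError("an outline needs at least 3 points")
        seg = np.diff(self.points, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise InputError("consecutive outline points must be distinct")
        for i in self.anchor_indices:
            if not 0 <= i < len(self.points):
                raise InputError(f"anchor index {i} out of range")


@dataclass
class LandmarkConfiguration:
    """k ordered semi-landmarks plus optional extra fixed landmarks."""

    coords: np.ndarray  # (k, 2)
    extra_points: np.ndarray | None = None  # (m, 2)
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.extra_points is not None:
            self.extra_points = np.atleast_2d(
                np.asarray(self.extra_points, dtype=float)
            )

    @property
    def all_points(self) -> np.ndarray:
        """Semi-landmarks with any extra landmarks appended."""
        if self.extra_points is None:
            return self.coords
        return np.vstack([self.coords, self.extra_points])

    @property
    def n_points(self) -> int:
        return len(self.all_points)


@dataclass
class ProcrustesResult:
    aligned: np.ndarray  # (n, k, 2), unit centroid size, centered
    centroid_sizes: np.ndarray  # original CS per specimen
    mean_shape: np.ndarray  # (k, 2), unit centroid size
    n_iterations: int
    converged: bool
    specimen_ids: list[str] = field(default_factory=list)


@dataclass
class RWResult:
    scores: np.ndarray  # (n, n_axes)
    variance_fraction: np.ndarray  # (n_axes,)
    axes: np.ndarray  # (n_axes, 2k) loading vectors
    mean_flat: np.ndarray  # (2k,) column means of flattened aligned coords


@dataclass
class RepeatabilityReport:
    feature_names: list[str]
    icc_values: np.ndarray
    threshold: float = 0.80

    @property
    def repeatable_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.icc_values > self.threshold


@dataclass
class PermanovaResult:
    F: float
    p: float | None
    n_perm: int
    SS_total: float
    SS_among: float
    SS_within: float
    seed: int | None = None


@dataclass
class ConfusionMatrix:
    labels: list
    counts: np.ndarray  # true x assigned
    flagged: list = field(default_factory=list)  # singleton-class rows

    @property
    def percent_correct(self) -> float:
        total = self.counts.sum()
        return 100.0 * np.trace(self.counts) / total if total else 0.0

    @property
    def per_label_percent(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * np.diag(self.counts) / row

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# semi-landmarking


def resample_outline(outline: Outline, k: int) -> LandmarkConfiguration:
    """Convert an outline to ``k`` semi-landmarks separated by equal arc length.

    Open curves place points at arc positions ``i*L/(k-1)`` so the two
    anchors are retained exactly; closed curves place points at
    ``i*L/k`` starting from the anchor vertex.
    """
    if k < 3:
        raise InputError("need k >= 3 semi-landmarks")
    pts = outline.points
    if outline.is_closed:
        start = outline.anchor_indices[0]
        pts = np.roll(pts, -start, axis=0)
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0.0:
        raise InputError("outline has zero total length")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if outline.is_closed:
        targets = np.arange(k) * total / k
    else:
        targets = np.arange(k) * total / (k - 1)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    return LandmarkConfiguration(coords=np.column_stack([x, y]))


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared distances to the centroid."""
    pts = config.all_points if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if len(pts) < 2:
        raise InputError("centroid size needs at least 2 points")
    dev = pts - pts.mean(axis=0)
    cs = float(np.sqrt((dev**2).sum()))
    if cs == 0.0:
        warnings.warn("all points coincide; centroid size is 0", stacklevel=2)
    return cs


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||a @ R - b|| (no reflection)."""
    u, _, vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def gpa(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> ProcrustesResult:
    """Generalized least-squares Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size, and
    iteratively rotated to the running consensus (proper rotations
    only); the consensus is recomputed and renormalized to unit centroid
    size until it stabilizes. Original centroid sizes are retained.
    """
    if len(configs) < 2:
        raise InputError("GPA needs at least 2 configurations")
    ks = {c.n_points for c in configs}
    if len(ks) != 1:
        raise InputError(f"configurations have mismatched landmark counts: {sorted(ks)}")
    ids = [c.specimen_id for c in configs]
    X = np.stack([c.all_points for c in configs]).astype(float)
    X -= X.mean(axis=1, keepdims=True)
    cs = np.sqrt((X**2).sum(axis=(1, 2)))
    if np.any(cs == 0):
        raise InputError("degenerate configuration with zero centroid size")
    X /= cs[:, None, None]

    mean = X[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(X)):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        new_mean = X.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        delta = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("GPA did not converge; returning partial result", stacklevel=2)
    return ProcrustesResult(
        aligned=X, centroid_sizes=cs, mean_shape=mean,
        n_iterations=it, converged=converged, specimen_ids=ids,
    )


def relative_warps(pr: ProcrustesResult, n_axes: int | None = None) -> RWResult:
    """Relative warps: PCA of the flattened Procrustes-aligned coordinates.

    Uses uniform shape-space weighting (no bending-energy exponent), so
    axes are ordinary principal components of the aligned coordinates.
    Sign convention: the largest-magnitude loading of each axis is
    positive. ``n_axes`` defaults to the full rank bound
    ``min(n_specimens - 1, 2k)``; the four near-null similarity
    dimensions then simply carry (numerically) zero variance.
    """
    n = pr.aligned.shape[0]
    if n < 3:
        raise InputError("relative warps need at least 3 specimens")
    flat = pr.aligned.reshape(n, -1)
    mean_flat = flat.mean(axis=0)
    centered = flat - mean_flat
    full = min(n - 1, flat.shape[1])
    if n_axes is None:
        n_axes = full
    n_axes = min(n_axes, full)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :full], s[:full], vt[:full]
    # fix axis signs so the largest-|loading| entry is positive
    for j in range(len(s)):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total = float((s**2).sum())
    if total < 1e-20:  # all shapes numerically identical
        frac = np.zeros(len(s))
        s = np.zeros_like(s)
        u = np.zeros_like(u)
    else:
        frac = (s**2) / total
    scores = u * s
    return RWResult(
        scores=scores[:, :n_axes],
        variance_fraction=frac[:n_axes],
        axes=vt[:n_axes],
        mean_flat=mean_flat,
    )


# ---------------------------------------------------------------------------
# repeatability


def icc(series1: np.ndarray, series2: np.ndarray) -> float:
    """Two-way absolute-agreement single-measure intraclass correlation.

    Computed from the n x 2 table of paired digitizations with specimen
    rows and series columns:
    ``ICC = (MS_R - MS_E) / (MS_R + MS_E + 2 (MS_C - MS_E) / n)``.
    """
    a = np.asarray(series1, float)
    b = np.asarray(series2, float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("series must be 1-D and of equal length")
    n = len(a)
    if n < 3:
        raise InputError("ICC needs at least 3 paired specimens")
    x = np.column_stack([a, b])
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = 2.0 * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = (resid**2).sum()
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / 1.0
    ms_e = ss_err / (n - 1)
    denom = ms_r + ms_e + 2.0 * (ms_c - ms_e) / n
    if denom == 0.0:
        warnings.warn("zero total variance; ICC undefined", stacklevel=2)
        return float("nan")
    return float((ms_r - ms_e) / denom)


def repeatability_report(
    features1: pd.DataFrame,
    features2: pd.DataFrame,
    threshold: float = 0.80,
) -> RepeatabilityReport:
    """ICC per shared feature column between two digitization series."""
    cols = [c for c in features1.columns if c in features2.columns]
    vals = np.array([icc(features1[c].to_numpy(), features2[c].to_numpy()) for c in cols])
    return RepeatabilityReport(feature_names=list(cols), icc_values=vals, threshold=threshold)


def select_repeatable(report: RepeatabilityReport, features: pd.DataFrame) -> pd.DataFrame:
    """Keep only feature columns whose ICC strictly exceeds the threshold."""
    missing = [c for c in features.columns if c not in report.feature_names]
    if missing:
        raise InputError(f"report does not cover features: {missing}")
    keep = [
        c for c in features.columns
        if report.icc_values[report.feature_names.index(c)] > report.threshold
    ]
    if not keep:
        raise InputError(
            f"no feature passed the repeatability threshold ICC > {report.threshold}"
        )
    return features[keep]


# ---------------------------------------------------------------------------
# classification


def _check_lda_inputs(features: pd.DataFrame, labels: np.ndarray) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise InputError("LDA needs at least 2 classes")
    pooled = []
    for c in classes:
        sub = features.to_numpy(float)[np.asarray(labels) == c]
        pooled.append(sub - sub.mean(axis=0))
    w = np.vstack(pooled)
    cov = w.T @ w / max(len(w) - len(classes), 1)
    if np.linalg.cond(cov) > 1e12:
        raise NumericalError(
            "pooled within-class covariance is singular; reduce the number "
            "of features or add specimens"
        )


def lda_fit_assign(
    features: pd.DataFrame,
    labels,
    query: pd.DataFrame,
    priors: np.ndarray | None = None,
):
    """Classic LDA assignment with pooled covariance and equal priors.

    Returns ``(assigned_labels, discriminant_scores)`` where scores are
    the per-class decision values for each query row.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise InputError(f"classes with fewer than 2 training rows: {list(small)}")
    if list(features.columns) != list(query.columns):
        raise InputError("query columns must match training columns")
    _check_lda_inputs(features, labels)
    if priors is None:
        priors = np.full(len(classes), 1.0 / len(classes))
    model = LinearDiscriminantAnalysis(priors=priors)
    model.fit(features.to_numpy(float), labels)
    q = query.to_numpy(float)
    assigned = model.predict(q)
    scores = model.decision_function(q)
    return assigned, scores


def jackknife_confusion(features: pd.DataFrame, labels) -> ConfusionMatrix:
    """Leave-one-out LDA cross-validation tabulated as a confusion matrix."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    label_ix = {c: i for i, c in enumerate(classes)}
    flagged = [c for c, n in zip(classes, counts) if n < 2]
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    X = features.to_numpy(float)
    for i in range(len(labels)):
        if counts[label_ix[labels[i]]] < 2:
            continue  # singleton class: cannot be left out and still trained on
        mask = np.ones(len(labels), bool)
        mask[i] = False
        train_labels = labels[mask]
        if len(np.unique(train_labels)) < 2:
            continue
        try:
            assigned, _ = lda_fit_assign(
                features.iloc[mask], train_labels, features.iloc[i : i + 1]
            )
        except InputError:
            flagged.append(labels[i])
            continue
        mat[label_ix[labels[i]], label_ix[assigned[0]]] += 1
    return ConfusionMatrix(labels=list(classes), counts=mat, flagged=sorted(set(flagged)))


# ---------------------------------------------------------------------------
# PerMANOVA


def _ss_within(d2: np.ndarray, codes: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        m = codes == g
        n_g = int(m.sum())
        ss += d2[np.ix_(m, m)].sum() / (2.0 * n_g)
    return ss


def permanova(
    features: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
    standardize: bool = False,
) -> PermanovaResult:
    """Distance-based permutational MANOVA on Euclidean distances.

    ``SS_total = (1/N) sum_{i<j} d_ij^2``; ``SS_within`` pools the
    analogous per-group terms; the pseudo-F statistic
    ``F = (SS_among/(a-1)) / (SS_within/(N-a))`` is referred to its
    permutation distribution under random reassignment of group labels
    (+1 convention, observed configuration counted).

    ``standardize`` z-scores the feature columns first, useful when a
    size variable in larger units would otherwise dominate the distances.
    """
    X = features.to_numpy(float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    codes, uniques = pd.factorize(np.asarray(groups))
    a = len(uniques)
    N = len(codes)
    if a < 2:
        raise InputError("PerMANOVA needs at least 2 groups")
    if np.any(np.bincount(codes) < 2):
        raise InputError("each group needs at least 2 rows")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    ss_total = d2.sum() / (2.0 * N)
    group_ids = np.arange(a)
    ss_within = _ss_within(d2, codes, group_ids)
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        raise NumericalError("zero within-group variation; pseudo-F undefined")
    f_obs = (ss_among / (a - 1)) / (ss_within / (N - a))

    p = None
    if n_perm >= 1:
        rng = np.random.default_rng(seed)
        # batch: permuted one-hot memberships against the fixed d2 matrix
        perms = np.argsort(rng.random((n_perm, N)), axis=1)
        perm_codes = codes[perms]  # (n_perm, N)
        ssw = np.zeros(n_perm)
        for g in group_ids:
            m = (perm_codes == g).astype(float)
            n_g = np.bincount(codes)[g]
            ssw += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * n_g)
        f_perm = ((ss_total - ssw) / (a - 1)) / (ssw / (N - a))
        p = float((1 + np.sum(f_perm >= f_obs)) / (n_perm + 1))
    return PermanovaResult(
        F=float(f_obs), p=p, n_perm=n_perm,
        SS_total=float(ss_total), SS_among=float(ss_among),
        SS_within=float(ss_within), seed=seed,
    )


def sequential_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down correction; returns reject decisions in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject
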