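"""Factor-analytic classification of receptor variants.

Pipeline mirroring the standard workflow for summarising heterologous
expression measurements of channel variants: impute missing cells by
low-rank completion on ranks, express every property as a log10 ratio to
wildtype with a sign convention where positive means gain of function,
check sampling adequacy (KMO), extract two rotated principal components,
and cluster the rotated scores with k-means (cluster number from the elbow
of the within-cluster sum-of-squares curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from grinsyn.stats import double_bootstrap_bca_ci, CorrelationResult
from grinsyn.tables import PropertyTable, PROPERTY_COLUMNS, INVERTED_COLUMNS

__all__ = [
    "RankALSImputer",
    "impute_missing",
    "log_ratio_table",
    "kmo_statistic",
    "varimax",
    "promax",
    "RotatedPCA",
    "FactorModel",
    "ClusterAssignment",
    "elbow_from_curve",
    "select_k_elbow",
    "kmeans_cluster",
    "classify_mutations",
]

LOG_COLUMNS = [
    "glu_potency",
    "gly_potency",
    "deact_tau",
    "current_density",
    "open_prob",
    "surface_rel",
]


# ---------------------------------------------------------------------------
# Imputation: rank transform -> ALS low-rank completion -> back interpolation
# ---------------------------------------------------------------------------

class RankALSImputer(TransformerMixin, BaseEstimator):
    """Single imputation by low-rank orthogonal regression on ranks.

    Each column is rank-transformed (average ranks over observed cells), the
    incomplete rank matrix is completed by rank-``n_components`` alternating
    least squares PCA, and completed ranks are mapped back to measurement
    units by piecewise-linear interpolation against the observed
    (rank, value) pairs of the column.  Completed ranks outside the observed
    range are clamped to the column extremes.  Observed cells are returned
    unchanged.

    The transformer is stateless: each matrix is completed on its own
    support, so ``fit`` only validates parameters.
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-6, max_iter: int = 500):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.n_components >= X.shape[1]:
            raise ValueError("n_components must be smaller than the number of properties")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        if not mask.any():
            return X.copy()
        if mask.all(axis=0).any():
            j = int(np.where(mask.all(axis=0))[0][0])
            raise ValueError(f"column {j} has no observed values")
        if (~mask).sum(axis=0).min() < 2:
            raise ValueError("each column needs at least 2 observed values for interpolation")

        ranks = np.full_like(X, np.nan)
        for j in range(X.shape[1]):
            obs = ~mask[:, j]
            ranks[obs, j] = rankdata(X[obs, j])

        completed = _als_complete(ranks, self.n_components, self.tol, self.max_iter)

        out = X.copy()
        for j in range(X.shape[1]):
            obs = ~mask[:, j]
            order = np.argsort(ranks[obs, j])
            r_obs = ranks[obs, j][order]
            v_obs = X[obs, j][order]
            miss = mask[:, j]
            out[miss, j] = np.interp(completed[miss, j], r_obs, v_obs)
        return out

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


def _als_complete(R: np.ndarray, rank: int, tol: float, max_iter: int) -> np.ndarray:
    """Complete a matrix with NaNs by alternating least squares at fixed rank."""
    mask = np.isnan(R)
    mu = np.nanmean(R, axis=0)
    Rc = R - mu
    filled = np.where(mask, 0.0, Rc)

    # initialize factors from the SVD of the mean-filled matrix
    U_, s, Vt = np.linalg.svd(filled, full_matrices=False)
    U = U_[:, :rank] * s[:rank]
    V = Vt[:rank].T

    obs = ~mask
    last = None
    change = np.inf
    for _ in range(max_iter):
        for i in range(R.shape[0]):
            o = obs[i]
            if o.any():
                U[i], *_ = np.linalg.lstsq(V[o], Rc[i, o], rcond=None)
        for j in range(R.shape[1]):
            o = obs[:, j]
            V[j], *_ = np.linalg.lstsq(U[o], Rc[o, j], rcond=None)
        est = U @ V.T
        imputed = est[mask]
        if last is not None:
            change = float(np.max(np.abs(imputed - last)))
            if change < tol:
                return np.where(mask, est + mu, R)
        last = imputed.copy()
    raise RuntimeError(
        f"ALS imputation did not converge in {max_iter} iterations "
        f"(last imputed-cell change {change:.3g})"
    )


def impute_missing(tbl: PropertyTable, n_components: int = 2, tol: float = 1e-6,
                   max_iter: int = 500) -> PropertyTable:
    """Return a complete copy of ``tbl`` (see :class:`RankALSImputer`)."""
    imp = RankALSImputer(n_components=n_components, tol=tol, max_iter=max_iter)
    filled = imp.fit_transform(tbl.data.to_numpy(dtype=float))
    data = pd.DataFrame(filled, index=tbl.data.index, columns=tbl.data.columns)
    return PropertyTable(data, tbl.wt.copy())


# ---------------------------------------------------------------------------
# Normalisation to WT on the log scale
# ---------------------------------------------------------------------------

def log_ratio_table(tbl: PropertyTable) -> pd.DataFrame:
    """log10 ratio to WT with gain-of-function positive for every column.

    EC50 columns are inverted into potencies (1/EC50) so that higher potency
    (lower EC50) is positive; the deactivation time constant enters
    un-inverted, so slower deactivation (a gain of channel activity) is
    positive.
    """
    if tbl.data.isna().any().any():
        raise ValueError("table has missing cells; impute first")
    out = {}
    for col, name in zip(PROPERTY_COLUMNS, LOG_COLUMNS):
        ratio = tbl.data[col] / tbl.wt[col]
        out[name] = -np.log10(ratio) if col in INVERTED_COLUMNS else np.log10(ratio)
    return pd.DataFrame(out, index=tbl.data.index)


# ---------------------------------------------------------------------------
# Sampling adequacy
# ---------------------------------------------------------------------------

def kmo_statistic(table) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum u_ij^2) over i != j, where r are
    Pearson correlations and u the anti-image (partial) correlations obtained
    from the inverse correlation matrix.  Values above 0.5 are conventionally
    considered adequate for factor extraction.
    """
    X = np.asarray(table, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("KMO needs at least 3 rows")
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("constant column: correlation matrix singular")
    R = np.corrcoef(X, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix singular") from e
    if np.any(np.diag(Rinv) <= 0):
        # numerically singular: fall back to the pseudo-inverse
        Rinv = np.linalg.pinv(R, rcond=1e-10)
        if np.any(np.diag(Rinv) <= 0):
            raise ValueError("correlation matrix singular")
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    U = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    u2 = np.sum(U[off] ** 2)
    return float(r2 / (r2 + u2))


# ---------------------------------------------------------------------------
# PCA with rotation
# ---------------------------------------------------------------------------

def varimax(loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 500):
    """Orthogonal varimax rotation; returns (rotated loadings, rotation matrix)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    R = np.eye(k)
    if k < 2:
        return L, R
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        tmp = Lr**3 - Lr * (np.sum(Lr**2, axis=0) / p)
        U, s, Vt = np.linalg.svd(L.T @ tmp)
        R = U @ Vt
        var_new = np.sum(s)
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    return L @ R, R


def promax(loadings: np.ndarray, power: int = 4):
    """Oblique promax rotation; returns (pattern matrix, rotation matrix, phi).

    Starts from the varimax solution, builds the target of element-wise
    powered loadings, and relaxes orthogonality by least squares; ``phi`` is
    the inter-factor correlation matrix.
    """
    Lv, Rv = varimax(loadings)
    h = np.sqrt(np.sum(Lv**2, axis=1))
    h[h == 0] = 1.0
    Ln = Lv / h[:, None]
    target = np.abs(Ln) ** power * np.sign(Ln)
    Q, *_ = np.linalg.lstsq(Lv, target, rcond=None)
    d = np.sqrt(np.clip(np.diag(np.linalg.inv(Q.T @ Q)), 1e-12, None))
    Q = Q * d
    pattern = Lv @ Q
    Qinv = np.linalg.inv(Q)
    phi = Qinv @ Qinv.T
    return pattern, Rv @ Q, phi


@dataclass
class FactorModel:
    """Rotated principal-component solution for a log-ratio table."""

    loadings: np.ndarray          # unrotated p x k
    rotation: np.ndarray          # k x k
    pattern: np.ndarray           # rotated p x k (pattern matrix)
    scores: np.ndarray            # n x k rotated component scores
    variance_fraction: np.ndarray  # length k, from eigenvalues/trace
    property_names: list = field(default_factory=list)


class RotatedPCA(TransformerMixin, BaseEstimator):
    """PCA on the correlation matrix with varimax or promax rotation.

    Columns are z-scored (so the eigendecomposition is of the correlation
    matrix), the first ``n_components`` loadings (eigenvectors scaled by the
    square root of their eigenvalues) are rotated, and scores are obtained by
    regressing the standardized data on the rotated pattern.

    Attributes (after ``fit``)
    --------------------------
    loadings_ : unrotated loadings, shape (p, k)
    pattern_ : rotated pattern matrix, shape (p, k)
    rotation_ : rotation matrix, shape (k, k)
    variance_fraction_ : eigenvalue fractions of the retained components
    phi_ : inter-factor correlation (promax only; identity for varimax)
    """

    def __init__(self, n_components: int = 2, rotation: str | None = "varimax"):
        self.n_components = n_components
        self.rotation = rotation

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        k = self.n_components
        if k > p:
            raise ValueError("n_components exceeds number of properties")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            raise ValueError("constant column: correlation matrix singular")
        R = np.corrcoef(X, rowvar=False)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if evals[k - 1] <= 1e-12 * max(evals[0], 1.0):
            raise ValueError("n_components exceeds the rank of the correlation matrix")
        # fix eigenvector sign so the largest-magnitude element is positive
        for j in range(p):
            i = np.argmax(np.abs(evecs[:, j]))
            if evecs[i, j] < 0:
                evecs[:, j] = -evecs[:, j]
        self.eigenvalues_ = evals
        self.variance_fraction_ = evals[:k] / evals.sum()
        self.loadings_ = evecs[:, :k] * np.sqrt(evals[:k])
        if self.rotation is None:
            self.pattern_, self.rotation_ = self.loadings_.copy(), np.eye(k)
            self.phi_ = np.eye(k)
        elif self.rotation == "varimax":
            self.pattern_, self.rotation_ = varimax(self.loadings_)
            self.phi_ = np.eye(k)
        elif self.rotation == "promax":
            self.pattern_, self.rotation_, self.phi_ = promax(self.loadings_)
        else:
            raise ValueError(f"unknown rotation {self.rotation!r}")
        # order rotated factors by explained sum of squared loadings
        ss = np.sum(self.pattern_**2, axis=0)
        order = np.argsort(ss)[::-1]
        self.pattern_ = self.pattern_[:, order]
        self.rotation_ = self.rotation_[:, order]
        self.phi_ = self.phi_[np.ix_(order, order)]
        self.n_features_in_ = p
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        P = self.pattern_
        return Z @ P @ np.linalg.inv(P.T @ P)

    def to_model(self, X, property_names=None) -> FactorModel:
        return FactorModel(
            loadings=self.loadings_.copy(),
            rotation=self.rotation_.copy(),
            pattern=self.pattern_.copy(),
            scores=self.transform(X),
            variance_fraction=self.variance_fraction_.copy(),
            property_names=list(property_names or []),
        )


def fit_factors(table, n_components: int = 2, rotation: str = "varimax") -> FactorModel:
    """Convenience wrapper fitting :class:`RotatedPCA` on a log-ratio table."""
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(np.asarray(table))
    est = RotatedPCA(n_components=n_components, rotation=rotation).fit(df.to_numpy(dtype=float))
    return est.to_model(df.to_numpy(dtype=float), property_names=list(df.columns))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    labels: np.ndarray
    centroids: np.ndarray
    within_ss: float
    within_ss_by_k: dict = field(default_factory=dict)


def _kmeans(scores, k, seed, n_init):
    return KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(scores)


def elbow_from_curve(within_ss, k_min: int = 1) -> int:
    """Elbow of a within-SS curve: k maximising the second difference of log(SS).

    ``within_ss`` maps k -> sum of squares (dict or sequence starting at k=1).
    The second difference is taken on the log of the curve, which locates the
    k where the sum of squares collapses (the kink) independently of the
    curve's absolute scale; on the raw curve the statistic is dominated by
    the large early drops whenever clusters are arranged symmetrically.
    A curve with fewer than 3 points returns ``k_min``.
    """
    if isinstance(within_ss, dict):
        ks = sorted(within_ss)
        w = np.array([within_ss[k] for k in ks], dtype=float)
    else:
        w = np.asarray(within_ss, dtype=float)
        ks = list(range(1, len(w) + 1))
    if len(w) < 3:
        return k_min
    logw = np.log(np.maximum(w, 1e-12 * max(w.max(), 1.0)))
    d2 = logw[:-2] - 2 * logw[1:-1] + logw[2:]
    return int(ks[1 + int(np.argmax(d2))])


def select_k_elbow(scores, k_max: int, seed: int = 0, n_init: int = 10,
                   k_min: int = 1, min_drop: float = 0.2):
    """Choose the cluster number from the k-means within-SS elbow.

    Runs k-means for k = 1..k_max and takes the k maximising the second
    difference of the log within-cluster sum of squares.  Degenerate-input
    policy: the elbow is accepted only if it reduces the within-SS below
    ``min_drop`` times the k=1 value (i.e. the clustering explains at least
    80% of the scatter by default); a single diffuse blob never reaches
    this, since k-means on an isotropic Gaussian explains at most ~70% at
    small k, and the configured minimum ``k_min`` is returned instead.
    Returns ``(k, within_ss_by_k)``.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k_max >= n:
        raise ValueError("k_max must be smaller than the number of points")
    wss = {}
    for k in range(1, k_max + 1):
        wss[k] = float(_kmeans(scores, k, seed, n_init).inertia_)
    if wss[1] == 0.0:
        return k_min, wss
    k_star = elbow_from_curve(wss, k_min=k_min)
    if wss[k_star] > min_drop * wss[1]:
        return k_min, wss
    return k_star, wss


def kmeans_cluster(scores, k: int, seed: int = 0, n_init: int = 100) -> ClusterAssignment:
    """Best-of-``n_init`` seeded k-means on factor scores."""
    scores = np.asarray(scores, dtype=float)
    if k > scores.shape[0]:
        raise ValueError("k cannot exceed the number of points")
    km = _kmeans(scores, k, seed, n_init)
    return ClusterAssignment(
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        within_ss=float(km.inertia_),
        within_ss_by_k={k: float(km.inertia_)},
    )


# ---------------------------------------------------------------------------
# End-to-end classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    table: PropertyTable          # imputed
    log_table: pd.DataFrame
    kmo: float
    factors: FactorModel
    clusters: ClusterAssignment
    k: int
    within_ss_by_k: dict
    factor_correlation: CorrelationResult | None


def classify_mutations(
    tbl: PropertyTable,
    n_components: int = 2,
    rotation: str = "varimax",
    k: int | None = None,
    k_max: int = 8,
    seed: int = 0,
    n_init: int = 100,
    impute_components: int = 2,
    bootstrap: bool = True,
    n_outer: int = 20000,
    n_inner: int = 200,
) -> ClassificationResult:
    """Full variant-classification pipeline.

    Imputes missing cells, normalises to WT on the log10 scale, extracts and
    rotates two principal components, clusters the rotated scores (k from the
    within-SS elbow unless given), and quantifies the inter-factor
    association by Kendall's tau-b with a coverage-calibrated double-bootstrap
    BCa confidence interval.
    """
    full = impute_missing(tbl, n_components=impute_components) if tbl.n_missing else tbl
    logt = log_ratio_table(full)
    kmo = kmo_statistic(logt.to_numpy())
    model = fit_factors(logt, n_components=n_components, rotation=rotation)
    if k is None:
        k, wss = select_k_elbow(model.scores, k_max=min(k_max, len(logt) - 1), seed=seed)
    else:
        wss = {}
    clusters = kmeans_cluster(model.scores, k=k, seed=seed, n_init=n_init)
    corr = None
    if bootstrap and model.scores.shape[1] >= 2:
        # inter-factor correlation is only meaningful on oblique scores:
        # regression scores from an orthogonal rotation are uncorrelated by
        # construction, so the association is always measured on the promax
        # solution (identical to model.scores when rotation="promax")
        osc = (model.scores if rotation == "promax"
               else fit_factors(logt, n_components, "promax").scores)
        corr = double_bootstrap_bca_ci(
            osc[:, 0], osc[:, 1], statistic="tau_b",
            n_outer=n_outer, n_inner=n_inner, seed=seed,
        )
    return ClassificationResult(full, logt, kmo, model, clusters, k, wss, corr)
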