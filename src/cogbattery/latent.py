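"""Latent-factor pipeline over the battery's 23 performance variables.

The pipeline follows the standard recipe for factor-analysing proportion
data: probit-transform the rates (inverse standard-normal CDF, with 0 and
1 clipped to 1/2N and 1 - 1/2N to avoid infinities), keep RT and
switch-cost variables in milliseconds, z-standardize every column over the
participant-day observations, then decompose with PCA (components ordered
by explained variance) and FastICA (order arbitrary, signs normalized so
each component's largest-magnitude loading is positive).  Variables are
finally grouped by average-linkage hierarchical clustering on the
correlation distance 1 - |cos| between their loading vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import EstimationError

logger = logging.getLogger(__name__)

DEFAULT_K = 6

#: The battery's 23 analysis variables: (column name, task, condition, metric).
#: Rate metrics are probit-transformed; rt / switch_cost stay in ms.
FEATURE_COLUMNS: list[tuple[str, str, str, str]] = [
    *[(f"enum_acc_set{n}", "enumeration", f"set{n}", "accuracy") for n in (5, 6, 7, 8, 9)],
    *[(f"mot_acc_speed{s}", "mot", f"speed{s}", "accuracy") for s in (1, 4, 8)],
    ("lib_acc_near", "lib", "near", "accuracy"),
    ("lib_acc_far", "lib", "far", "accuracy"),
    *[(f"wm_acc_len{n}", "corsi", f"len{n}", "accuracy") for n in (4, 5, 6, 7, 8)],
    ("mem_hr_short", "memorability", "short", "hr"),
    ("mem_hr_long", "memorability", "long", "hr"),
    ("mem_far", "memorability", "first", "far"),
    ("gng_hr", "gonogo", "go", "hr"),
    ("gng_far", "gonogo", "nogo", "far"),
    ("gng_rt", "gonogo", "go", "rt"),
    ("switch_cost_odd_even", "switch", "odd_even", "switch_cost"),
    ("switch_cost_high_low", "switch", "high_low", "switch_cost"),
]

RATE_METRICS = ("accuracy", "hr", "far")


def probit(p, n_trials):
    """Inverse-normal transform of a proportion with boundary correction.

    Returns Phi^-1(p') where p' clips p = 0 to 1/(2N) and p = 1 to
    1 - 1/(2N), N being the trial count behind the proportion.  Accepts
    scalars or arrays (broadcast together).
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n_trials)
    if np.any(n < 1):
        raise ValueError("n_trials must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    eps = 1.0 / (2.0 * n)
    clipped = np.clip(p, eps, 1.0 - eps)
    out = stats.norm.ppf(clipped)
    return float(out) if out.ndim == 0 else out


@dataclass
class FeatureMatrix:
    """Observations (participant-day) x 23 variables, standardized.

    ``data`` holds the z-scored values used for decomposition; ``raw``
    holds the probit/ms values before standardization.  ``column_info``
    maps each column to (task, condition, metric).
    """

    data: pd.DataFrame
    raw: pd.DataFrame
    column_info: dict
    means: pd.Series
    sds: pd.Series

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)


def build_feature_matrix(
    scores: pd.DataFrame,
    columns: list[tuple[str, str, str, str]] | None = None,
) -> FeatureMatrix:
    """Assemble the analysis matrix from a tidy score table.

    ``scores`` is the table produced by :func:`cogbattery.scoring.score_table`
    (columns participant_id, day, task, condition, metric, value, k, n).
    Rows are participant-day observations; a row missing any variable is
    dropped with a logged warning.  Standardization uses the sample SD
    (ddof=1) so that the covariance of the standardized matrix equals the
    correlation matrix exactly.
    """
    columns = columns or FEATURE_COLUMNS
    indexed = scores.set_index(["participant_id", "day", "task", "condition", "metric"])

    obs_keys = sorted(set(zip(scores["participant_id"], scores["day"])))
    rows, raw_rows, kept = [], [], []
    for pid, day in obs_keys:
        vals = {}
        ok = True
        for name, task, condition, metric in columns:
            try:
                rec = indexed.loc[(pid, day, task, condition, metric)]
            except KeyError:
                ok = False
                break
            value = float(rec["value"])
            if metric in RATE_METRICS:
                value = probit(value, int(rec["n"]))
            if not np.isfinite(value):
                ok = False
                break
            vals[name] = value
        if ok:
            raw_rows.append(vals)
            kept.append(f"{pid}_d{day}")
        else:
            logger.warning("dropping observation %s day %s: missing variables", pid, day)
    if not raw_rows:
        raise ValueError("no complete observations")

    raw = pd.DataFrame(raw_rows, index=kept, columns=[c[0] for c in columns])
    means = raw.mean()
    sds = raw.std(ddof=1)
    zero_var = sds[sds == 0.0].index.tolist()
    if zero_var:
        logger.warning("constant columns left unscaled: %s", zero_var)
    safe_sds = sds.replace(0.0, 1.0)
    data = (raw - means) / safe_sds
    info = {name: (task, cond, metric) for name, task, cond, metric in columns}
    return FeatureMatrix(data=data, raw=raw, column_info=info, means=means, sds=sds)


@dataclass
class FactorModel:
    method: str  # "pca" | "ica"
    k: int
    loadings: pd.DataFrame  # variables x components
    scores: np.ndarray  # observations x components
    explained_variance: np.ndarray | None = None  # percent, PCA only
    scree: np.ndarray | None = None  # percent per component over all columns
    non_gaussianity: np.ndarray | None = None  # |excess kurtosis| per IC
    feature_names: list | None = None


def fit_pca(X: FeatureMatrix, k: int = DEFAULT_K) -> FactorModel:
    """Principal components of the standardized matrix.

    Loadings are the unit-norm eigenvectors of the sample correlation
    matrix, ordered by explained variance; scores are the projections of
    the standardized observations.  The full scree (all columns) is always
    attached so the component count can be re-chosen from the elbow.
    """
    n_obs, n_var = X.data.shape
    if k < 1 or k > n_var:
        raise ValueError(f"k must be in 1..{n_var}, got {k}")
    m = min(n_obs, n_var)
    full = PCA(n_components=m)
    full.fit(X.values)
    rank = int(np.linalg.matrix_rank(X.values - X.values.mean(axis=0)))
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    # eigenvalues beyond the rank are exactly zero; pad so the scree always
    # spans all columns
    scree = np.zeros(n_var)
    scree[:m] = full.explained_variance_ratio_ * 100.0
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X.values)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=X.feature_names,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return FactorModel(
        method="pca",
        k=k,
        loadings=loadings,
        scores=scores,
        explained_variance=scree[:k],
        scree=scree,
        feature_names=X.feature_names,
    )


def fit_ica(
    X: FeatureMatrix,
    k: int = DEFAULT_K,
    seed: int = 0,
    max_iter: int = 1000,
    restarts: int = 1,
) -> FactorModel:
    """FastICA with k components after whitening.

    Component order carries no meaning; the sign of each component is
    normalized so its largest-magnitude loading is positive.  Components
    whose recovered source is nearly Gaussian (|excess kurtosis| close to
    zero) are not identifiable and should be treated as unreliable; the
    per-component non-Gaussianity is attached for that purpose.

    The fixed-point iteration can stall on small or nearly-Gaussian data;
    ``restarts`` retries with consecutive derived seeds (seed, seed+1, ...)
    before giving up, which keeps the fit deterministic for a given seed.
    """
    n_var = X.data.shape[1]
    if k < 1 or k > n_var:
        raise ValueError(f"k must be in 1..{n_var}, got {k}")
    sources = ica = None
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        for attempt in range(max(1, restarts)):
            ica = FastICA(
                n_components=k, random_state=seed + attempt,
                whiten="unit-variance", max_iter=max_iter,
            )
            try:
                sources = ica.fit_transform(X.values)
                break
            except ConvergenceWarning:
                continue
        if sources is None:
            raise EstimationError(
                f"FastICA did not converge within the iteration budget of "
                f"{max_iter} ({max(1, restarts)} restarts)"
            )
    mixing = ica.mixing_.copy()  # variables x k
    for j in range(k):
        if mixing[np.argmax(np.abs(mixing[:, j])), j] < 0:
            mixing[:, j] *= -1.0
            sources[:, j] *= -1.0
    loadings = pd.DataFrame(
        mixing, index=X.feature_names, columns=[f"IC{i + 1}" for i in range(k)]
    )
    non_gauss = np.abs(stats.kurtosis(sources, axis=0, fisher=True))
    return FactorModel(
        method="ica",
        k=k,
        loadings=loadings,
        scores=sources,
        non_gaussianity=non_gauss,
        feature_names=X.feature_names,
    )


@dataclass
class ClusterTree:
    linkage: np.ndarray  # scipy linkage matrix, (n_vars - 1, 4)
    labels: list  # variable names in input order
    leaf_order: list  # variable names in dendrogram order

    def cut(self, n_clusters: int) -> dict:
        """Variable name -> cluster id (1-based) at the given cut."""
        assignment = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assignment)))


def cluster_loadings(model: FactorModel) -> ClusterTree:
    """Average-linkage agglomeration of variables on loading similarity.

    Distance between two variables is 1 - |cosine| of their loading
    vectors, so variables loading on the same components cluster together
    regardless of sign.
    """
    if model.k < 1:
        raise ValueError("model has no components")
    L = model.loadings.to_numpy()
    norms = np.linalg.norm(L, axis=1)
    norms[norms == 0.0] = 1.0
    unit = L / norms[:, None]
    sim = np.abs(unit @ unit.T)
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = list(model.loadings.index)
    order = hierarchy.leaves_list(Z)
    return ClusterTree(linkage=Z, labels=labels, leaf_order=[labels[i] for i in order])
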