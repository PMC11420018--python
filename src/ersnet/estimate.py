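"""Network estimation: EBIC-glasso partial-correlation networks, walktrap
communities, and the mixed graphical model over strategies and symptoms.

The exploratory-graph-analysis (EGA) route is ``correlation_matrix`` ->
``ebic_glasso`` -> ``walktrap_communities``: a graphical-lasso path is fit on
the item Pearson correlations, the extended BIC selects the penalty, and
walktrap communities of the resulting partial-correlation network play the
role of factors.

The mixed graphical model (MGM) over the 22 network variables (6 continuous
strategy sum-scores + 16 ordinal 0-3 symptom codes) is estimated by nodewise
lasso regressions on standardized variables with per-node cross-validated
penalties, aggregated into a symmetric edge weight matrix.  Ordinal symptoms
enter the regressions as their integer codes; this keeps every conditional
linear-Gaussian so the fitted model is directly usable as a Gibbs sampler
(see :mod:`ersnet.esa`), at the price of ignoring category-specific effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .items import ItemResponseMatrix, NodeMeta
from .network import CommunityPartition, WeightedNetwork, partition_from_labels

logger = logging.getLogger(__name__)

#: partial correlations below this magnitude are treated as exact zeros
#: (graphical-lasso iterates leave numerical dust on shrunk entries).
EDGE_EPS = 1e-4


@dataclass
class EstimationSettings:
    """Hyperparameters shared by the two estimators.

    ``ebic_gamma`` is the extended-BIC hyperparameter (0.5 is the standard
    EGA default); the lasso path uses ``n_lambda`` log-spaced penalties with
    min/max ratio ``lambda_min_ratio``.  ``cv_folds``/``cv_seed`` control the
    nodewise cross-validation of the mixed model; ``edge_rule`` is the
    AND/OR aggregation of the two directed nodewise coefficients.
    """

    ebic_gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    cv_folds: int = 10
    cv_seed: int = 0
    edge_rule: str = "AND"
    cv_rule: str = "min"  # "min": smallest CV error; "1se": sparsest within 1 SE
    glasso_tol: float = 1e-3
    glasso_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.ebic_gamma < 0:
            raise ValueError("ebic_gamma must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.edge_rule not in ("AND", "OR"):
            raise ValueError("edge_rule must be 'AND' or 'OR'")
        if self.cv_rule not in ("min", "1se"):
            raise ValueError("cv_rule must be 'min' or '1se'")


def correlation_matrix(data, method: str = "pearson") -> pd.DataFrame:
    """Correlation matrix of item responses or score columns.

    ``data`` may be an :class:`ItemResponseMatrix` or any DataFrame/array of
    numeric columns.  Constant columns are rejected by name because their
    correlation is undefined.
    """
    if isinstance(data, ItemResponseMatrix):
        frame = data.to_frame()
    else:
        frame = pd.DataFrame(data)
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    constant = [str(c) for c in frame.columns if frame[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant column(s) with zero variance: {constant}")
    corr = frame.corr(method=method)
    return corr


def ebic_score(loglik: float, n_edges: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC of a fitted Gaussian graphical model with E edges."""
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)


def _nearest_pd_correlation(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    repaired = (vecs * np.maximum(vals, eps)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    return repaired / np.outer(d, d)


def ebic_glasso(
    corr,
    n: int,
    settings: EstimationSettings | None = None,
    node_ids: list[str] | None = None,
) -> WeightedNetwork:
    """Graphical-lasso path on a correlation matrix, selected by extended BIC.

    Each penalty ``lam`` on a log-spaced grid yields a precision estimate;
    the fit minimizing

        EBIC = -2 loglik + E log(n) + 4 gamma E log(p)

    (E = number of nonzero edges) is returned as its partial-correlation
    network.  Penalties at which the glasso iterations fail to converge are
    skipped.
    """
    settings = settings or EstimationSettings()
    if isinstance(corr, pd.DataFrame):
        node_ids = node_ids or [str(c) for c in corr.columns]
        corr = corr.to_numpy(dtype=float)
    corr = np.asarray(corr, dtype=float)
    p = corr.shape[0]
    node_ids = node_ids or [f"v{i}" for i in range(p)]
    if n <= 0:
        raise ValueError("n must be positive")
    if settings.n_lambda < 1:
        raise ValueError("empty lambda grid")

    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < 0:
        logger.info("correlation matrix not PSD (min eig %.3g); applying nearest-PD repair", eigmin)
        corr = _nearest_pd_correlation(corr)

    offdiag = np.abs(corr[np.triu_indices(p, k=1)])
    lam_max = max(float(offdiag.max(initial=0.0)), 1e-4)
    grid = np.logspace(
        np.log10(lam_max), np.log10(lam_max * settings.lambda_min_ratio), settings.n_lambda
    )

    iu = np.triu_indices(p, k=1)
    best = None
    best_ebic = np.inf
    for lam in grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, precision = graphical_lasso(
                    corr,
                    alpha=float(lam),
                    max_iter=settings.glasso_max_iter,
                    tol=settings.glasso_tol,
                )
        except FloatingPointError:
            continue
        d = np.sqrt(np.diag(precision))
        pcor = -precision / np.outer(d, d)
        np.fill_diagonal(pcor, 0.0)
        pcor[np.abs(pcor) < EDGE_EPS] = 0.0
        n_edges = int(np.count_nonzero(pcor[iu]))
        sign, logdet = np.linalg.slogdet(precision)
        if sign <= 0:
            continue
        loglik = 0.5 * n * (logdet - float(np.sum(precision * corr)))
        ebic = ebic_score(loglik, n_edges, n, p, settings.ebic_gamma)
        if ebic < best_ebic:
            best_ebic = ebic
            best = pcor
    if best is None:
        raise RuntimeError("graphical lasso failed to converge on the whole penalty grid")
    best = np.clip((best + best.T) / 2.0, -1.0, 1.0)
    return WeightedNetwork(node_ids=node_ids, weights=best, estimator_tag="ebic_glasso")


def walktrap_communities(net: WeightedNetwork, steps: int = 4) -> CommunityPartition:
    """Walktrap communities of a weighted network.

    The random walk uses absolute edge weights (sign carries no meaning for
    walk probabilities); the dendrogram is cut at maximum modularity.
    Isolated nodes each form their own community.
    """
    if net.p == 0:
        raise ValueError("empty network")
    sources, targets = np.triu_indices(net.p, k=1)
    w = np.abs(net.weights[sources, targets])
    keep = w > 0
    g = ig.Graph(
        n=net.p,
        edges=list(zip(sources[keep].tolist(), targets[keep].tolist())),
    )
    g.es["weight"] = w[keep].tolist()
    dendrogram = g.community_walktrap(weights="weight" if keep.any() else None, steps=steps)
    clustering = dendrogram.as_clustering()
    return partition_from_labels(net.node_ids, clustering.membership)


def _check_duplicates(frame: pd.DataFrame) -> None:
    corr = frame.corr().to_numpy()
    p = corr.shape[0]
    iu = np.triu_indices(p, k=1)
    dup = np.abs(corr[iu]) > 0.999
    if dup.any():
        i = int(iu[0][np.argmax(dup)])
        j = int(iu[1][np.argmax(dup)])
        raise ValueError(
            f"columns {frame.columns[i]!r} and {frame.columns[j]!r} are (near-)duplicates "
            f"(|r| > 0.999); remove one before estimation"
        )


def estimate_mgm(
    table: pd.DataFrame,
    nodes: list[NodeMeta],
    settings: EstimationSettings | None = None,
) -> WeightedNetwork:
    """Mixed graphical model via nodewise cross-validated lasso regressions.

    All columns are z-scored with training statistics; each node is then
    regressed on all others with a lasso whose penalty is chosen by
    ``cv_folds``-fold cross-validation (folds shuffled with ``cv_seed``).
    The two directed coefficients of a pair are aggregated into one edge:
    under the AND rule the edge is their mean when both are nonzero with the
    same sign and 0 otherwise; under the OR rule it is the mean of the
    nonzero ones.  Nonzero sign-conflicting pairs are zeroed and counted in
    ``sign_conflicts``.
    """
    settings = settings or EstimationSettings()
    node_ids = [m.node_id for m in nodes]
    if list(table.columns) != node_ids:
        table = table[node_ids]
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if n < 50:
        raise ValueError(f"need at least 50 rows to estimate the mixed model, got {n}")
    _check_duplicates(table)

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    if np.any(sds == 0):
        bad = node_ids[int(np.argmax(sds == 0))]
        raise ValueError(f"constant column {bad!r}")
    Z = (X - means) / sds

    beta = np.zeros((p, p))  # beta[i, j]: coefficient of node j predicting node i
    resid_sd = np.zeros(p)
    cv = KFold(n_splits=settings.cv_folds, shuffle=True, random_state=settings.cv_seed)
    for i in range(p):
        others = [j for j in range(p) if j != i]
        model = LassoCV(cv=cv, alphas=60, max_iter=5000, random_state=settings.cv_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Z[:, others], Z[:, i])
        coef = model.coef_
        if settings.cv_rule == "1se":
            mse = model.mse_path_.mean(axis=1)
            se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
            k_min = int(np.argmin(mse))
            limit = mse[k_min] + se[k_min]
            # alphas_ is decreasing; the first index within one SE is sparsest
            k_1se = int(np.argmax(mse <= limit))
            refit = Lasso(alpha=float(model.alphas_[k_1se]), max_iter=5000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                refit.fit(Z[:, others], Z[:, i])
            coef = refit.coef_
            model = refit
        beta[i, others] = coef
        resid = Z[:, i] - model.predict(Z[:, others])
        resid_sd[i] = max(float(resid.std(ddof=0)), 1e-6)

    weights = np.zeros((p, p))
    conflicts = 0
    for i in range(p):
        for j in range(i + 1, p):
            a, b = beta[i, j], beta[j, i]
            if a != 0.0 and b != 0.0:
                if np.sign(a) == np.sign(b):
                    w = (a + b) / 2.0
                else:
                    conflicts += 1
                    w = 0.0
            elif settings.edge_rule == "OR":
                w = a + b  # at most one nonzero
            else:
                w = 0.0
            weights[i, j] = weights[j, i] = w
    if conflicts:
        logger.warning("%d sign-conflicting coefficient pairs zeroed", conflicts)

    return WeightedNetwork(
        node_ids=node_ids,
        weights=weights,
        estimator_tag="mgm",
        kinds=[m.kind for m in nodes],
        groups={m.node_id: m.group for m in nodes},
        means=means,
        sds=sds,
        residual_sd=resid_sd,
        sign_conflicts=conflicts,
    )
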