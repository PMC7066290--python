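"""IsoSVM classification and group statistics.

The classifier embeds the feature table with Isomap (k-nearest-neighbor
graph on z-scored Euclidean feature distances, geodesics via all-pairs
shortest paths, classical MDS on the geodesic matrix) and trains a linear
support vector machine on the embedded coordinates.  Class imbalance is
handled by multiplying the misclassification cost of the benign class
(label 0) by a penalty ratio; the ratio is selected by a leave-one-out
cross-validated grid search over ``{1, 1.5, 2, 2.5, 3, 3.5, 4} : 1``,
keeping the ratio with the maximum LOOCV AUC (ties broken toward the
smaller, more parsimonious ratio).  The sensitivity/specificity operating
point is the Youden-optimal ROC threshold on the LOOCV scores.

Embedding modes: by default Isomap is fit once on all subjects and only
the SVM is cross-validated (transductive); ``embed_per_fold=True``
re-embeds the training set in every fold and places the held-out subject
by its mean geodesic distances (strict out-of-sample mode).

ROC analysis uses the Mann–Whitney (midrank) AUC with a DeLong variance
estimate for the 95% confidence interval.  Group statistics per feature:
mean ± SEM per class, Welch's two-sided unpaired t-test, univariate
logistic regression by maximum likelihood, and the per-feature AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.neighbors import kneighbors_graph
from sklearn.svm import SVC

__all__ = [
    "FeatureTable",
    "IsoSVMConfig",
    "isomap_embed",
    "fit_weighted_svm",
    "loocv_grid_search",
    "roc_analysis",
    "group_stats",
]

DEFAULT_PENALTY_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass(frozen=True)
class FeatureTable:
    """Per-subject named feature values with a binary class label.

    Labels: 0 = benign-like, 1 = malignant-like.  Feature names are
    identical across subjects and no value may be missing.
    """

    subject_ids: tuple[str, ...]
    labels: np.ndarray
    features: pd.DataFrame  # rows align with subject_ids

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        if not np.isin(labels, [0, 1]).all():
            raise ValueError("labels must be 0 (benign) or 1 (malignant)")
        if len(self.subject_ids) != len(labels) or len(labels) != len(self.features):
            raise ValueError("subject_ids, labels and features must align")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        df = self.features if names is None else self.features[names]
        return df.to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        df = self.features.copy()
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", list(self.subject_ids))
        return df.reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        if "subject_id" not in df or "label" not in df:
            raise ValueError("frame must have subject_id and label columns")
        feats = df.drop(columns=["subject_id", "label"])
        return cls(tuple(str(s) for s in df["subject_id"]),
                   df["label"].to_numpy(), feats.reset_index(drop=True))


@dataclass(frozen=True)
class IsoSVMConfig:
    """IsoSVM hyperparameters.

    ``k`` neighbors for the Isomap graph (default 20), ``d_embed``
    embedding dimensions (default 1), ``penalty_grid`` benign:malignant
    misclassification cost ratios searched by LOOCV.
    """

    k: int = 20
    d_embed: int = 1
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID
    C: float = 1.0
    embed_per_fold: bool = False

    def __post_init__(self):
        if self.k < 1 or self.d_embed < 1:
            raise ValueError("k and d_embed must be >= 1")
        if any(r < 1 for r in self.penalty_grid):
            raise ValueError("penalty ratios must be >= 1")


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _geodesic_matrix(x: np.ndarray, k: int) -> np.ndarray:
    """All-pairs geodesic distances on the symmetrized k-NN graph.

    A disconnected graph is repaired by adding, between each pair of
    components, the shortest Euclidean inter-component edge, until one
    component remains.
    """
    n = len(x)
    graph = kneighbors_graph(x, n_neighbors=min(k, n - 1), mode="distance")
    # duplicate points sit at distance 0; an explicit sparse zero would be
    # read as "no edge", so clamp to a negligible positive length before
    # symmetrization canonicalizes the zeros away
    graph.data = np.maximum(graph.data, 1e-12)
    graph = graph.maximum(graph.T).tolil()
    n_comp, labels = connected_components(graph.tocsr(), directed=False)
    while n_comp > 1:
        euclid = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
        best = None
        for a in range(n_comp):
            for b in range(a + 1, n_comp):
                ia = np.where(labels == a)[0]
                ib = np.where(labels == b)[0]
                sub = euclid[np.ix_(ia, ib)]
                pos = np.unravel_index(np.argmin(sub), sub.shape)
                cand = (sub[pos], ia[pos[0]], ib[pos[1]])
                if best is None or cand[0] < best[0]:
                    best = cand
        _, u, v = best
        graph[u, v] = graph[v, u] = best[0]
        n_comp, labels = connected_components(graph.tocsr(), directed=False)
    return shortest_path(graph.tocsr(), method="D", directed=False)


def _classical_mds(dist: np.ndarray, d_embed: int) -> np.ndarray:
    n = len(dist)
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals[:d_embed], 0.0, None)
    coords = vecs[:, :d_embed] * np.sqrt(vals)[None, :]
    # deterministic sign: largest-magnitude loading positive per axis
    for c in range(coords.shape[1]):
        col = coords[:, c]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    return coords


def isomap_embed(
    x: np.ndarray, k: int = 20, d_embed: int = 1, standardize: bool = True
) -> np.ndarray:
    """Isomap embedding of an (n_subjects, n_features) matrix.

    Features are z-scored first (heterogeneous feature families live on
    very different scales).  Requires more subjects than neighbors.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = len(x)
    if n <= k:
        raise ValueError(f"need more subjects than neighbors (n={n}, k={k})")
    if standardize:
        x = _zscore(x)
    return _classical_mds(_geodesic_matrix(x, k), d_embed)


def fit_weighted_svm(
    embedded: np.ndarray, labels: np.ndarray, ratio: float, C: float = 1.0
) -> SVC:
    """Linear SVM with the benign-class cost multiplied by ``ratio``.

    Returns the fitted estimator; ``decision_function`` gives signed
    scores oriented so larger means more malignant-like.
    """
    embedded = np.asarray(embedded, dtype=float)
    if embedded.ndim == 1:
        embedded = embedded[:, None]
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    clf = SVC(kernel="linear", C=C, class_weight={0: float(ratio), 1: 1.0})
    clf.fit(embedded, labels)
    return clf


def _loocv_scores(
    x_embed: np.ndarray, y: np.ndarray, ratio: float, C: float
) -> np.ndarray:
    n = len(y)
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        clf = fit_weighted_svm(x_embed[tr], y[tr], ratio, C)
        scores[i] = clf.decision_function(x_embed[i:i + 1])[0]
    return scores


def _loocv_scores_strict(
    x: np.ndarray, y: np.ndarray, ratio: float, cfg: IsoSVMConfig
) -> np.ndarray:
    """Re-embed per fold; the held-out point is placed by landmark MDS."""
    n = len(y)
    scores = np.empty(n)
    idx = np.arange(n)
    xz = _zscore(x)
    for i in range(n):
        tr = idx != i
        xt = xz[tr]
        geo = _geodesic_matrix(xt, min(cfg.k, len(xt) - 1))
        coords = _classical_mds(geo, cfg.d_embed)
        clf = fit_weighted_svm(coords, y[tr], ratio, cfg.C)
        # landmark placement: geodesic distances from the held-out point
        # approximated by Euclidean hop to nearest training point + geodesics
        d_test = np.linalg.norm(xt - xz[i], axis=1)
        nearest = np.argmin(d_test)
        d_geo = d_test[nearest] + geo[nearest]
        d_geo[nearest] = d_test[nearest]
        # Gower interpolation onto the training embedding
        d2_mean = (geo**2).mean(axis=0)
        b = -0.5 * (d_geo**2 - d2_mean - (geo**2).mean() + d2_mean.mean())
        lam = (coords**2).sum(axis=0)
        lam = np.where(lam > 0, lam, 1.0)
        test_coord = (coords.T @ b) / lam
        scores[i] = clf.decision_function(test_coord[None, :])[0]
    return scores


def loocv_grid_search(
    table: FeatureTable | tuple[np.ndarray, np.ndarray],
    config: IsoSVMConfig | None = None,
    feature_names: list[str] | None = None,
) -> dict:
    """Leave-one-out grid search over imbalance penalty ratios.

    For each ratio, LOOCV decision scores are computed and their AUC taken;
    the ratio with maximum AUC wins (ties to the smaller ratio).  Returns
    the best ratio, the per-subject LOOCV scores under it, the full ROC
    analysis (AUC, DeLong CI, Youden sensitivity/specificity) and the AUC
    per candidate ratio.
    """
    if config is None:
        config = IsoSVMConfig()
    if isinstance(table, FeatureTable):
        x = table.matrix(feature_names)
        y = table.labels
    else:
        x, y = np.asarray(table[0], float), np.asarray(table[1], int)
        if x.ndim == 1:
            x = x[:, None]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if len(y) < 10:
        raise ValueError("need at least 10 subjects for LOOCV grid search")
    if not config.embed_per_fold:
        x_embed = isomap_embed(x, config.k, config.d_embed)
    per_ratio = {}
    best = None
    for ratio in config.penalty_grid:
        if config.embed_per_fold:
            scores = _loocv_scores_strict(x, y, ratio, config)
        else:
            scores = _loocv_scores(x_embed, y, ratio, config.C)
        auc = _auc_midrank(scores, y)
        per_ratio[ratio] = auc
        if best is None or auc > best[1] + 1e-12:
            best = (ratio, auc, scores)
    best_ratio, _, best_scores = best
    roc = roc_analysis(best_scores, y)
    return {
        "best_ratio": float(best_ratio),
        "scores": best_scores,
        "auc_per_ratio": per_ratio,
        **roc,
    }


def _auc_midrank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC with midranks for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    n1, n0 = len(pos), len(neg)
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC estimate (single-curve case)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # structural components via midrank placements
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n          # P(neg < pos_i)
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # P(pos > neg_j)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> dict:
    """AUC (midrank Mann–Whitney), DeLong 95% CI, ROC points, Youden point.

    The ROC curve is traced over all distinct score thresholds; the
    operating point maximizes Youden's J = sensitivity + specificity - 1
    (ties broken toward higher sensitivity).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = _auc_midrank(scores, labels)
    var = _delong_variance(scores, labels)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    # ROC points: threshold at each distinct score (predict 1 if score >= t)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    tpr = np.array([(scores[labels == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[labels == 0] >= t).mean() for t in thresholds])
    j = tpr - fpr
    k = int(np.argmax(j))
    return {
        "auc": auc,
        "auc_ci95": ci,
        "roc_points": np.column_stack([fpr, tpr]),
        "thresholds": thresholds,
        "youden_threshold": float(thresholds[k]),
        "sensitivity": float(tpr[k]),
        "specificity": float(1.0 - fpr[k]),
        "n_pos": int(n_pos),
        "n_neg": int(n_neg),
    }


def group_stats(table: FeatureTable, feature: str) -> dict:
    """Per-feature group comparison: mean ± SEM, Welch t, logistic fit, AUC.

    A feature with zero variance in both groups has no defined t statistic;
    the t-test entries are flagged NaN while the AUC is still computed
    (it degenerates to 0.5 under the midrank convention).
    """
    vals = table.features[feature].to_numpy(dtype=float)
    y = table.labels
    g0, g1 = vals[y == 0], vals[y == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("both classes need n >= 2")
    out = {
        "mean_benign": float(g0.mean()),
        "sem_benign": float(g0.std(ddof=1) / np.sqrt(len(g0))),
        "mean_malignant": float(g1.mean()),
        "sem_malignant": float(g1.std(ddof=1) / np.sqrt(len(g1))),
    }
    if g0.std(ddof=1) == 0 and g1.std(ddof=1) == 0:
        out["t_statistic"] = float("nan")
        out["p_value"] = float("nan")
        out["t_test_defined"] = False
    else:
        t, p = sps.ttest_ind(g1, g0, equal_var=False)
        out["t_statistic"] = float(t)
        out["p_value"] = float(p)
        out["t_test_defined"] = True
    out.update(_univariate_logistic(vals, y))
    roc = roc_analysis(vals, y)
    out["auc"] = roc["auc"]
    out["auc_ci95"] = roc["auc_ci95"]
    return out


def _univariate_logistic(vals: np.ndarray, y: np.ndarray) -> dict:
    import statsmodels.api as sm

    sd = vals.std(ddof=1)
    if sd == 0:
        return {"logit_coef": float("nan"), "logit_p": float("nan")}
    z = (vals - vals.mean()) / sd
    xmat = sm.add_constant(z)
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, xmat).fit(disp=0, maxiter=200)
        # likelihood-ratio p: unlike the Wald test it stays informative
        # when the classes are (quasi-)separated and the coefficient and
        # its standard error both diverge
        return {"logit_coef": float(fit.params[1]),
                "logit_p": float(fit.llr_pvalue)}
    except Exception:
        # perfect separation and similar non-convergence
        return {"logit_coef": float("inf"), "logit_p": 0.0}
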