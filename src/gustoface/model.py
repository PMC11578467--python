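"""Taste/score classification and measure-importance ranking.

Features are the per-video SD vectors of the 12 rescaled measures.
Importance is ranked two ways and cross-checked:

* an extremely-randomised-trees ensemble (200 trees, sqrt(p) features
  per split, min 5 samples to split, min 2 per leaf) using its native
  impurity-based importances, averaged over several refit seeds because
  single-seed tree importances are unstable at cohort-sized n;
* a principal-component procedure: features standardised, then ranked
  by absolute loadings aggregated over components weighted by explained
  variance.

Classification accuracy is evaluated with subject-grouped
cross-validation so no child contributes to both training and test
folds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.model_selection import GroupKFold

from .errors import EmptySeriesError, ValidationError
from .measures import MEASURE_NAMES
from .stats import VideoSummary, summaries_frame

log = logging.getLogger(__name__)

#: Ensemble hyperparameters as stated for the reference analysis.
TREES_PARAMS = dict(n_estimators=200, max_features="sqrt",
                    min_samples_split=5, min_samples_leaf=2)

Label = Literal["taste", "hedonic_score"]


@dataclass
class FeatureMatrix:
    """Video-by-measure SD features with labels and subject grouping."""

    X: pd.DataFrame               # index video_id, columns = MEASURE_NAMES
    taste: pd.Series
    hedonic_score: pd.Series
    groups: pd.Series             # subject_id per row
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if list(self.X.columns) != list(MEASURE_NAMES):
            raise ValidationError("feature columns must be the canonical measure order")
        if self.X.isna().any().any():
            raise ValidationError("feature matrix contains missing values")

    def labels(self, label: Label) -> pd.Series:
        if label == "taste":
            return self.taste
        if label == "hedonic_score":
            return self.hedonic_score
        raise ValidationError(f"unknown label {label!r}")


@dataclass
class ImportanceRanking:
    """Measure importances and the induced ranking.

    ``weights`` is indexed by measure in canonical order; ``ranking`` is
    the measure names sorted by descending weight, ties broken by the
    canonical column order (stable sort).
    """

    weights: pd.Series
    method: str                   # "trees" or "pca"
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if (self.weights < -1e-12).any():
            raise ValidationError("importance weights must be >= 0")

    @property
    def ranking(self) -> list[str]:
        order = np.argsort(-self.weights.to_numpy(), kind="stable")
        return [self.weights.index[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"measure": self.weights.index, "weight": self.weights.values})
        df["rank"] = df["weight"].rank(ascending=False, method="first").astype(int)
        df["method"] = self.method
        return df.sort_values("rank").reset_index(drop=True)


def build_features(summaries: Sequence[VideoSummary]) -> FeatureMatrix:
    """Assemble the video-by-measure feature matrix, dropping unusable rows."""
    if not summaries:
        raise EmptySeriesError("no summaries given")
    df = summaries_frame(summaries).set_index("video_id")
    X = df[list(MEASURE_NAMES)]
    keep = ~X.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d video(s) with undefined SDs", n_dropped)
    if not keep.any():
        raise EmptySeriesError("all rows dropped while building features")
    df = df[keep]
    return FeatureMatrix(X=df[list(MEASURE_NAMES)].astype(float),
                         taste=df["taste"], hedonic_score=df["hedonic_score"],
                         groups=df["subject_id"], n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# importance rankings
# ---------------------------------------------------------------------------

def rank_importance_trees(matrix: FeatureMatrix, label: Label = "taste",
                          n_seeds: int = 20, base_seed: int = 0) -> ImportanceRanking:
    """Mean impurity-based importances over ``n_seeds`` ensemble refits.

    Deterministic given ``base_seed`` (refit seeds are base_seed ..
    base_seed + n_seeds - 1); weights sum to 1.
    """
    y = matrix.labels(label)
    if y.nunique() < 2:
        raise ValidationError(f"label {label!r} has a single class")
    if len(matrix.X) < 10:
        raise ValidationError("need at least 10 rows to rank importances")
    seeds = tuple(range(base_seed, base_seed + n_seeds))
    acc = np.zeros(len(MEASURE_NAMES))
    for s in seeds:
        clf = ExtraTreesClassifier(random_state=s, **TREES_PARAMS)
        clf.fit(matrix.X.to_numpy(), y.to_numpy())
        acc += clf.feature_importances_
    w = acc / acc.sum()
    return ImportanceRanking(weights=pd.Series(w, index=list(MEASURE_NAMES)),
                             method="trees", seeds=seeds)


def rank_importance_pca(matrix: FeatureMatrix) -> ImportanceRanking:
    """PCA-based ranking by communality on the retained components.

    Features are standardised internally, so the ranking is invariant to
    affine rescaling of any column.  Components are retained by the
    Kaiser criterion (eigenvalue of the correlation matrix > 1, i.e.
    directions carrying more variance than any single standardised
    feature); at least one is always retained.  Each feature is scored
    by its communality over that set — the variance of the feature
    explained by the retained components, sum_k lambda_k * loading_kj^2
    — which concentrates weight on features aligned with the dominant
    shared structure.  Over *all* components this sum is exactly 1 for
    every standardised feature, so trailing components carry no ranking
    information, only noise.  Zero-variance columns are excluded with a
    warning (weight 0).  Component signs are fixed so the
    largest-magnitude loading of each component is positive; squared
    loadings make the rank sign-independent regardless.
    """
    X = matrix.X.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        log.warning("PCA ranking: excluding %d zero-variance column(s)", int((~keep).sum()))
    if keep.sum() < 2:
        raise ValidationError("PCA ranking needs at least 2 non-constant columns")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(svd_solver="full")
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    # eigenvalues of the correlation matrix; ddof-0 standardisation above
    eigvals = pca.explained_variance_ * (len(Z) - 1) / len(Z)
    n_keep = max(int((eigvals > 1.0).sum()), 1)
    load = pca.components_[:n_keep]   # (k, p)
    flip = np.sign(load[np.arange(load.shape[0]), np.argmax(np.abs(load), axis=1)])
    load = load * flip[:, None]
    w_kept = eigvals[:n_keep] @ load ** 2
    w = np.zeros(len(MEASURE_NAMES))
    w[keep] = w_kept / w_kept.sum()
    return ImportanceRanking(weights=pd.Series(w, index=list(MEASURE_NAMES)), method="pca")


def compare_rankings(a: ImportanceRanking, b: ImportanceRanking, k: int = 3) -> dict:
    """Top-k overlap fraction and Spearman rank correlation between rankings."""
    if set(a.weights.index) != set(b.weights.index):
        raise ValidationError("rankings cover different measure sets")
    top_a, top_b = set(a.ranking[:k]), set(b.ranking[:k])
    overlap = len(top_a & top_b) / k
    ra = pd.Series(range(len(a.ranking)), index=a.ranking)
    rb = pd.Series(range(len(b.ranking)), index=b.ranking)
    rho = float(spearmanr(ra[a.weights.index], rb[a.weights.index]).statistic)
    return {"k": k, "top_k_overlap": overlap, "top_k_common": sorted(top_a & top_b),
            "spearman_rho": rho, "method_a": a.method, "method_b": b.method}


# ---------------------------------------------------------------------------
# subject-grouped cross-validated classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    label: str
    accuracy: float
    per_class_accuracy: pd.Series
    confusion: pd.DataFrame       # rows true, columns predicted
    n_folds: int
    chance_level: float


def classify_cv(matrix: FeatureMatrix, label: Label = "taste", folds: int = 5,
                seed: int = 0) -> ClassificationReport:
    """Subject-grouped cross-validated accuracy with the stated ensemble.

    No subject appears in both the training and test side of any fold.
    """
    y = matrix.labels(label).astype(str)
    if y.nunique() < 2:
        raise ValidationError(f"label {label!r} has a single class")
    n_subjects = matrix.groups.nunique()
    if n_subjects < folds:
        raise ValidationError(f"{n_subjects} subjects < {folds} folds")
    classes = sorted(y.unique())
    X = matrix.X.to_numpy()
    yv = y.to_numpy()
    cm = pd.DataFrame(0, index=classes, columns=classes)
    cv = GroupKFold(n_splits=folds)
    for tr, te in cv.split(X, yv, groups=matrix.groups.to_numpy()):
        clf = ExtraTreesClassifier(random_state=seed, **TREES_PARAMS)
        clf.fit(X[tr], yv[tr])
        pred = clf.predict(X[te])
        for t, p in zip(yv[te], pred):
            cm.loc[t, p] += 1
    total = cm.to_numpy().sum()
    acc = float(np.trace(cm.to_numpy()) / total)
    per_class = pd.Series({c: (cm.loc[c, c] / cm.loc[c].sum()) if cm.loc[c].sum() else np.nan
                           for c in classes})
    return ClassificationReport(label=label, accuracy=acc, per_class_accuracy=per_class,
                                confusion=cm, n_folds=folds,
                                chance_level=1.0 / len(classes))
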