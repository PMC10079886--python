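"""Cohort-level feature analysis: standardization, group distances, LDA.

Each recording contributes a six-dimensional feature vector: the five
mixture features (mu_low, sigma_low, mu_high, sigma_high, w_high) of the
proposed method plus the conventional overall mean mu_total of the raw
acceleration norm. Features are z-scored over the pooled cohort before any
group contrast, so Euclidean distances between group means and linear
discriminant accuracies are comparable across feature subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix

from .errors import (ConfigError, ConsistencyError, DegenerateDesignError,
                     DegenerateFeatureError, InsufficientDataError)
from .segmentation import IN_PLAY, IntervalSet
from .signal_io import ALL_FEATURES, GMM_FEATURES, FeatureTable, TriaxialTrace
from .preprocess import vector_norm


def conventional_mean(trace: TriaxialTrace, intervals: IntervalSet,
                      whole_recording: bool = False) -> float:
    """Mean of the unfiltered acceleration norm (mu_total), in G.

    By default the mean is restricted to the in-play samples so the
    conventional feature sees the same exposure window as the mixture
    features; ``whole_recording=True`` averages over the full recording.
    """
    norm = vector_norm(trace).values
    if whole_recording:
        return float(norm.mean())
    if intervals.n_samples != len(trace):
        raise ConsistencyError(
            f"intervals cover {intervals.n_samples} samples, trace has {len(trace)}"
        )
    mask = intervals.labels() == IN_PLAY
    if not mask.any():
        raise InsufficientDataError("no in-play samples to average over")
    return float(norm[mask].mean())


def standardize(table: FeatureTable) -> FeatureTable:
    """Z-score every feature column over all rows (both groups pooled).

    Uses the n-1 (sample) standard deviation. Column means and sds are
    stored on the result so the transform is exactly invertible.
    """
    if len(table) < 2:
        raise InsufficientDataError("standardization needs at least 2 rows")
    df = table.data.copy()
    means, sds = {}, {}
    for col in ALL_FEATURES:
        m = float(df[col].mean())
        s = float(df[col].std(ddof=1))
        if s == 0.0 or not np.isfinite(s):
            raise DegenerateFeatureError(f"feature column {col!r} is constant")
        df[col] = (df[col] - m) / s
        means[col], sds[col] = m, s
    return FeatureTable(data=df, standardized=True,
                        column_means=means, column_sds=sds)


def unstandardize(table: FeatureTable) -> FeatureTable:
    """Invert :func:`standardize` using the stored column means/sds."""
    if not table.standardized:
        return table
    df = table.data.copy()
    for col in ALL_FEATURES:
        df[col] = df[col] * table.column_sds[col] + table.column_means[col]
    return FeatureTable(data=df, standardized=False)


def _check_features(features) -> list:
    features = list(features)
    if not features:
        raise ConfigError("empty feature subset")
    unknown = set(features) - set(ALL_FEATURES)
    if unknown:
        raise ConfigError(f"unknown feature name(s): {sorted(unknown)}")
    return features


def _two_groups(table: FeatureTable):
    groups = table.groups
    if len(groups) != 2:
        raise ConfigError(f"expected exactly two groups, got {groups}")
    return groups


def group_distance(table: FeatureTable, features) -> float:
    """Euclidean distance between the two group-mean vectors."""
    features = _check_features(features)
    if not table.standardized:
        raise ConfigError("group_distance requires a standardized table")
    ga, gb = _two_groups(table)
    means = table.data.groupby("group")[features].mean()
    return float(np.linalg.norm(means.loc[ga].to_numpy()
                                - means.loc[gb].to_numpy()))


def distance_matrix(table: FeatureTable) -> dict:
    """Group distances for every singleton and pair of the five mixture features.

    Returns ``{"singletons": {...}, "pairs": {...}, "best_pair": (f1, f2),
    "best_pair_distance": float}`` where pair keys are sorted feature-name
    tuples and ``best_pair`` maximizes the distance.
    """
    singles = {f: group_distance(table, [f]) for f in GMM_FEATURES}
    pairs = {tuple(sorted(p)): group_distance(table, list(p))
             for p in combinations(GMM_FEATURES, 2)}
    best = max(pairs, key=lambda p: pairs[p])
    return {"singletons": singles, "pairs": pairs,
            "best_pair": best, "best_pair_distance": pairs[best]}


@dataclass
class LDAModel:
    """Two-class linear discriminant with equal priors."""

    features: list
    classes: list
    weights: np.ndarray
    intercept: float
    accuracy: float
    confusion: np.ndarray  # rows: true class, cols: predicted
    predictions: pd.DataFrame = field(repr=False, default=None)

    def decision_scores(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept


def fit_lda(table: FeatureTable, features) -> LDAModel:
    """Fisher/pooled-covariance LDA with equal priors; resubstitution accuracy."""
    features = _check_features(features)
    if not table.standardized:
        raise ConfigError("fit_lda requires a standardized table")
    classes = _two_groups(table)
    counts = table.data["group"].value_counts()
    if counts.min() < 2:
        raise InsufficientDataError("each class needs at least 2 rows")
    X = table.data[features].to_numpy(dtype=float)
    y = table.data["group"].to_numpy()
    lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    try:
        lda.fit(X, y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DegenerateDesignError(
            f"singular pooled covariance for features {features}; "
            "try a smaller feature subset"
        ) from exc
    pred = lda.predict(X)
    acc = float((pred == y).mean())
    conf = confusion_matrix(y, pred, labels=list(lda.classes_))
    preds = pd.DataFrame({"recording_id": table.data["recording_id"],
                          "group": y, "predicted": pred,
                          "score": lda.decision_function(X)})
    return LDAModel(features=features, classes=list(lda.classes_),
                    weights=lda.coef_.ravel().copy(),
                    intercept=float(lda.intercept_[0]),
                    accuracy=acc, confusion=conf, predictions=preds)


PROPOSED_FEATURES = ["mu_high", "sigma_high"]
CONVENTIONAL_FEATURES = ["mu_total"]


def compare_methods(table: FeatureTable) -> dict:
    """Contrast the mixture high-side features against the overall mean.

    Bundles the Euclidean group distance and LDA resubstitution accuracy
    for the proposed feature pair {mu_high, sigma_high} and the
    conventional singleton {mu_total}, plus the full distance matrix over
    the five mixture features.
    """
    report = {}
    for name, feats in (("proposed", PROPOSED_FEATURES),
                        ("conventional", CONVENTIONAL_FEATURES)):
        model = fit_lda(table, feats)
        report[name] = {
            "features": list(feats),
            "distance": group_distance(table, feats),
            "accuracy": model.accuracy,
            "confusion": model.confusion.tolist(),
        }
    report["distance_matrix"] = distance_matrix(table)
    report["groups"] = table.groups
    report["n_rows"] = len(table)
    return report


def build_feature_table(rows: list[dict]) -> FeatureTable:
    """Assemble a raw FeatureTable from per-recording feature dicts."""
    return FeatureTable(data=pd.DataFrame(rows))
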