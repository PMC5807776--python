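"""scikit-learn-compatible wrapper around the top-scoring-pair classifier.

The TSP method is rank-based and parameter-free apart from the number of
pairs that vote, which makes it a natural scikit-learn estimator: ``fit``
runs the exhaustive pair scan on the training samples, ``predict`` applies
the majority vote of the fitted pairs. Follows the samples-as-rows
convention of scikit-learn (the reverse of the gene x sample matrices used
elsewhere in this package).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .tsp import tsp_classify, tsp_scan


class TopScoringPairClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier voting on within-sample expression-order reversals.

    Parameters
    ----------
    top_k : int
        Number of top-ranked gene pairs that vote.
    positive : label or None
        Class treated as class 1 (orientation reference); defaults to the
        first label encountered in ``y``.

    Attributes
    ----------
    pairs_ : list of TSPPair
        Fitted oriented pairs (gene indices or names as strings).
    scan_ : TSPScanResult
        Full scan result, including the maximum delta and pair counts.
    classes_ : ndarray
        The two class labels.
    """

    def __init__(self, top_k: int = 1, positive=None):
        self.top_k = top_k
        self.positive = positive

    def fit(self, X, y):
        feature_names = None
        if isinstance(X, pd.DataFrame):
            feature_names = [str(c) for c in X.columns]
        X, y = check_X_y(X, y, dtype=float)
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("TopScoringPairClassifier is strictly binary")
        self.n_features_in_ = X.shape[1]
        if feature_names is None:
            feature_names = [f"g{i}" for i in range(X.shape[1])]
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        expr = pd.DataFrame(X.T, index=feature_names)
        positive = self.positive if self.positive is not None else y[0]
        self.scan_ = tsp_scan(expr, y, top_k=self.top_k, positive=positive)
        self.pairs_ = self.scan_.pairs
        self.class_order_ = self.scan_.classes
        self.class_sizes_ = self.scan_.class_sizes
        return self

    def predict(self, X):
        check_is_fitted(self, "pairs_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        expr = pd.DataFrame(X.T, index=list(self.feature_names_in_))
        predicted, _, _ = tsp_classify(
            expr,
            self.pairs_,
            classes=self.class_order_,
            class_sizes=self.class_sizes_,
        )
        return predicted

    def decision_delta(self) -> float:
        """Maximum pair score achieved on the training data."""
        check_is_fitted(self, "scan_")
        return self.scan_.max_delta
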