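"""Scikit-learn-style estimators wrapping the subtype-assignment machinery.

Two classifiers are provided:

* :class:`PCACentroidClassifier` — a flat (single decision node) classifier:
  supervised PCA on the training matrix, nearest centroid under the
  variance-weighted Euclidean distance, inverse-distance membership
  probabilities.
* :class:`HierarchicalSubtypeClassifier` — the full nested workflow: one
  PCA-centroid decision per hierarchy node, restricted to that node's
  classifier genes, descending from the root until a leaf subtype.

Both follow sklearn conventions (``fit``/``predict``/``predict_proba``,
``get_params``/``set_params``, trailing-underscore fitted attributes) and
compose with sklearn model selection.  Like nearest-neighbour models they
keep the training matrix: in merge mode the PCA basis is refit for every
unknown, so prediction needs the raw reference expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .classify import (
    DEFAULT_OUTLIER_THRESHOLD,
    NodeResult,
    PredictionResult,
    classify_hierarchical,
    classify_node,
)
from .errors import ParameterError
from .hierarchy import SubtypeHierarchy
from .io import ExpressionMatrix, LabeledReference
from .reference import DEFAULT_COVERAGE_THRESHOLD, ReferenceModel, build_reference

_SIGMA_DDOF = {"n": 0, "n-1": 1}


def _as_frame(X, context: str) -> pd.DataFrame:
    """Coerce X to a samples x genes DataFrame with string identifiers."""
    if isinstance(X, pd.DataFrame):
        frame = X.copy()
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return frame
    arr = np.asarray(X, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.ndim != 2:
        raise ParameterError(f"{context}: X must be 2-d (samples x genes)")
    return pd.DataFrame(
        arr,
        index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"g{j}" for j in range(arr.shape[1])],
    )


class PCACentroidClassifier(ClassifierMixin, BaseEstimator):
    """Single-node supervised-PCA nearest-centroid classifier.

    Parameters
    ----------
    mode : "merge" or "project"
        "merge" (default) refits the PCA on training samples + the unknown
        for every prediction, as the published workflow does; "project"
        freezes the basis at fit time.
    n_components : int or "all"
        Components retained; "all" keeps every component.
    sigma_divisor : "n" or "n-1"
        Divisor of the within-class distance standard deviation.
    class_order : list of str, optional
        Declared class order, used to break exact distance ties; defaults to
        first appearance in ``y``.
    """

    def __init__(
        self,
        mode: str = "merge",
        n_components: int | str = "all",
        sigma_divisor: str = "n",
        class_order: list[str] | None = None,
    ):
        self.mode = mode
        self.n_components = n_components
        self.sigma_divisor = sigma_divisor
        self.class_order = class_order

    def _ddof(self) -> int:
        if self.sigma_divisor not in _SIGMA_DDOF:
            raise ParameterError(
                f"sigma_divisor must be 'n' or 'n-1', got {self.sigma_divisor!r}"
            )
        return _SIGMA_DDOF[self.sigma_divisor]

    def fit(self, X, y):
        frame = _as_frame(X, type(self).__name__)
        y = np.asarray(y, dtype=object)
        if len(y) != len(frame):
            raise ParameterError(f"y has {len(y)} labels for {len(frame)} samples")
        labels = [str(v) for v in y]
        if self.class_order is not None:
            order = list(self.class_order)
            extra = sorted(set(labels) - set(order))
            if extra:
                raise ParameterError(f"labels {extra} not in class_order")
        else:
            order = list(dict.fromkeys(labels))
        matrix = ExpressionMatrix.from_frame(frame.T)
        self.model_ = ReferenceModel(
            node_id="node",
            classifier_genes=list(frame.columns),
            ref_matrix=matrix,
            child_labels=order,
            sample_child=dict(zip(matrix.sample_ids, labels)),
        )
        self.classes_ = np.array(sorted(set(labels)), dtype=object)
        self.n_features_in_ = frame.shape[1]
        return self

    def decision_details(self, x: pd.Series) -> NodeResult:
        """Full per-class distances, probabilities and relative distances for
        one sample (gene-indexed Series)."""
        check_is_fitted(self, "model_")
        return classify_node(
            self.model_,
            x,
            mode=self.mode,
            n_components=self.n_components,
            sigma_ddof=self._ddof(),
        )

    def _rows(self, X) -> list[pd.Series]:
        frame = _as_frame(X, type(self).__name__)
        return [frame.iloc[i] for i in range(len(frame))]

    def predict(self, X):
        return np.array(
            [self.decision_details(x).assigned_child for x in self._rows(X)], dtype=object
        )

    def predict_proba(self, X):
        out = np.zeros((0, len(self.classes_)))
        rows = []
        for x in self._rows(X):
            probs = self.decision_details(x).probabilities
            rows.append([probs[c] for c in self.classes_])
        return np.array(rows) if rows else out


class HierarchicalSubtypeClassifier(ClassifierMixin, BaseEstimator):
    """Nested subtype assignment by per-node supervised PCA.

    Parameters
    ----------
    classifier_sets : dict node_id -> list of gene ids
        Pre-derived classifier genes for every hierarchy node.
    hierarchy : SubtypeHierarchy, nested dict, or None
        The decision tree; None selects the default two-level glioma
        hierarchy (root {O, G}; O -> {OA, OB}; G -> {GA1, GA2, GB1, GB2}).
    mode, n_components, sigma_divisor : as in :class:`PCACentroidClassifier`.
    outlier_threshold : float
        Flag a prediction when the assigned child's relative distance r_D
        exceeds this at any level (default 3, a 3-sigma convention).
    coverage_threshold : float
        Maximum tolerated fraction of absent classifier genes per node.

    ``fit`` expects a samples x genes DataFrame (gene ids as columns) and a
    vector of leaf subtype labels.
    """

    def __init__(
        self,
        classifier_sets: dict[str, list[str]] | None = None,
        hierarchy=None,
        mode: str = "merge",
        n_components: int | str = "all",
        sigma_divisor: str = "n",
        outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
        coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    ):
        self.classifier_sets = classifier_sets
        self.hierarchy = hierarchy
        self.mode = mode
        self.n_components = n_components
        self.sigma_divisor = sigma_divisor
        self.outlier_threshold = outlier_threshold
        self.coverage_threshold = coverage_threshold

    def _resolve_hierarchy(self) -> SubtypeHierarchy:
        if self.hierarchy is None:
            return SubtypeHierarchy.default_glioma()
        if isinstance(self.hierarchy, SubtypeHierarchy):
            return self.hierarchy
        return SubtypeHierarchy.from_dict(self.hierarchy)

    def _ddof(self) -> int:
        if self.sigma_divisor not in _SIGMA_DDOF:
            raise ParameterError(
                f"sigma_divisor must be 'n' or 'n-1', got {self.sigma_divisor!r}"
            )
        return _SIGMA_DDOF[self.sigma_divisor]

    def fit(self, X, y):
        if self.classifier_sets is None:
            raise ParameterError("classifier_sets is required")
        frame = _as_frame(X, type(self).__name__)
        y = np.asarray(y, dtype=object)
        if len(y) != len(frame):
            raise ParameterError(f"y has {len(y)} labels for {len(frame)} samples")
        hierarchy = self._resolve_hierarchy()
        reference = LabeledReference(
            ExpressionMatrix.from_frame(frame.T),
            {s: str(v) for s, v in zip(frame.index, y)},
        )
        self.hierarchy_ = hierarchy
        self.models_ = build_reference(
            reference, hierarchy, self.classifier_sets, self.coverage_threshold
        )
        self.classes_ = np.array(sorted(hierarchy.leaves()), dtype=object)
        self.n_features_in_ = frame.shape[1]
        return self

    @classmethod
    def from_reference(
        cls,
        reference: LabeledReference,
        hierarchy: SubtypeHierarchy,
        classifier_sets: dict[str, list[str]],
        **params,
    ) -> "HierarchicalSubtypeClassifier":
        """Fit directly from a genes x samples labeled reference."""
        est = cls(classifier_sets=classifier_sets, hierarchy=hierarchy, **params)
        frame = reference.matrix.to_frame().T
        return est.fit(frame, [reference.labels[s] for s in frame.index])

    # -- prediction ---------------------------------------------------------

    def predict_result(self, x: pd.Series, sample_id: str | None = None) -> PredictionResult:
        """Full root-to-leaf prediction with per-node detail for one sample."""
        check_is_fitted(self, "models_")
        return classify_hierarchical(
            self.models_,
            self.hierarchy_,
            x,
            sample_id=sample_id or str(getattr(x, "name", None) or "unknown"),
            mode=self.mode,
            n_components=self.n_components,
            sigma_ddof=self._ddof(),
            coverage_threshold=self.coverage_threshold,
            outlier_threshold=self.outlier_threshold,
        )

    def node_result(self, node_id: str, x: pd.Series) -> NodeResult:
        """Assignment at one named node, regardless of the root decision."""
        check_is_fitted(self, "models_")
        return classify_node(
            self.models_[node_id],
            x,
            mode=self.mode,
            n_components=self.n_components,
            sigma_ddof=self._ddof(),
            coverage_threshold=self.coverage_threshold,
        )

    def _rows(self, X) -> list[pd.Series]:
        frame = _as_frame(X, type(self).__name__)
        return [frame.iloc[i] for i in range(len(frame))]

    def predict(self, X):
        return np.array(
            [self.predict_result(x).final_subtype for x in self._rows(X)], dtype=object
        )

    def predict_proba(self, X):
        """Leaf probabilities as products of per-node membership shares along
        each leaf's path; rows sum to 1 because each node's shares do."""
        check_is_fitted(self, "models_")
        rows = []
        for x in self._rows(X):
            node_probs = {
                node_id: self.node_result(node_id, x).probabilities
                for node_id in self.models_
            }
            row = []
            for leaf in self.classes_:
                p = 1.0
                for node, label in self.hierarchy_.leaf_path(str(leaf)):
                    p *= node_probs[node.node_id][label]
                row.append(p)
            rows.append(row)
        return np.array(rows)
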