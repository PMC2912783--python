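"""Weighted-distance subtype assignment.

The assignment machinery, per decision node:

* the unknown profile is merged into the node's reference submatrix and a
  covariance PCA is fit on the combined matrix (merge mode; project mode
  instead projects the unknown onto a basis fit on the reference alone);
* the distance between two samples is the weighted Euclidean distance on PC
  scores, d(U, V) = sqrt(sum_i w_i (u_i - v_i)^2), with w the per-component
  proportion of variance — components that explain more variation count for
  more;
* the membership probability of child subtype C_i is the normalized inverse
  distance to its centroid, p(U, C_i) = d(U, C̄_i)^-1 / sum_j d(U, C̄_j)^-1 —
  an ordinal confidence share, not a generative posterior;
* the relative distance r_D(U, C_i) = d(U, C̄_i) / sigma_i, where sigma_i is
  the standard deviation of the child's own sample-to-centroid distances,
  flags outliers in units of that subtype's dispersion.

The unknown never contributes to centroids or sigma; only reference samples
define child statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DegenerateModelError, ParameterError
from .hierarchy import SubtypeHierarchy
from .pca import PCAProjection, fit_pca, merge_and_project
from .reference import (
    DEFAULT_COVERAGE_THRESHOLD,
    ReferenceModel,
    centroid,
    resolve_coverage,
)

#: default outlier rule: flag when r_D of the assigned child exceeds 3
DEFAULT_OUTLIER_THRESHOLD = 3.0

_UNKNOWN_ID = "__unknown__"


# ---------------------------------------------------------------------------
# Elementary formulas
# ---------------------------------------------------------------------------

def weighted_distance(u, v, w) -> float:
    """Weighted Euclidean distance sqrt(sum_i w_i (u_i - v_i)^2)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if not (u.shape == v.shape == w.shape):
        raise ParameterError(
            f"length mismatch: |u|={u.shape}, |v|={v.shape}, |w|={w.shape}"
        )
    if (w < 0).any():
        raise ParameterError("weights must be non-negative")
    return float(np.sqrt(np.sum(w * (u - v) ** 2)))


def membership_probabilities(distances: dict[str, float]) -> dict[str, float]:
    """Normalized inverse-distance shares over >= 2 child subtypes.

    A single zero distance gets probability 1 (the d -> 0 limit of the
    formula); several zero distances are ill-posed.
    """
    if len(distances) < 2:
        raise ParameterError("need at least 2 child subtypes")
    d = np.array([distances[c] for c in distances], dtype=np.float64)
    if (d < 0).any():
        raise ParameterError("distances must be non-negative")
    zeros = d == 0.0
    if zeros.sum() > 1:
        raise DegenerateModelError(
            "several child centroids coincide with the sample; probabilities undefined"
        )
    if zeros.any():
        p = zeros.astype(np.float64)
    else:
        inv = 1.0 / d
        p = inv / inv.sum()
    return {c: float(pi) for c, pi in zip(distances, p)}


def relative_distance(d: float, sigma: float) -> float:
    """Distance to a centroid in units of the subtype's own dispersion."""
    if d < 0:
        raise ParameterError(f"distance must be non-negative, got {d}")
    if sigma <= 0:
        raise DegenerateModelError(
            "sigma of within-subtype distances is zero: the subtype's reference "
            "samples coincide, so the relative distance is undefined; add reference "
            "samples with nonzero spread or remove the degenerate subtype"
        )
    return float(d / sigma)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class NodeResult:
    """Outcome of one decision node."""

    node_id: str
    distances: dict[str, float]
    probabilities: dict[str, float]
    relative_distances: dict[str, float]
    assigned_child: str
    weights: np.ndarray
    pc3_unknown: list[float]
    pc3_reference: dict[str, list[float]]  # sample id -> first-3-PC coords
    child_of_sample: dict[str, str]  # reference sample id -> child label
    warnings: list[str] = field(default_factory=list)


@dataclass
class PredictionResult:
    """Root-to-leaf classification of one unknown sample."""

    sample_id: str
    node_results: list[NodeResult]
    final_subtype: str
    outlier_flag: bool
    outlier_rule: str

    @property
    def path(self) -> list[str]:
        return [r.assigned_child for r in self.node_results]


# ---------------------------------------------------------------------------
# Node-level assignment
# ---------------------------------------------------------------------------

def _align_unknown(
    model: ReferenceModel,
    unknown: pd.Series,
    coverage_threshold: float,
) -> tuple[ReferenceModel, np.ndarray, list[str]]:
    """Apply the missing-gene policy between the unknown and the node's
    classifier genes; returns (possibly gene-restricted model, unknown vector,
    warnings)."""
    notes: list[str] = []
    genes = model.classifier_genes
    missing = [g for g in genes if g not in unknown.index]
    if missing:
        genes = resolve_coverage(
            genes,
            set(unknown.index),
            coverage_threshold,
            context=f"node {model.node_id!r} vs unknown sample",
        )
        notes.append(
            f"dropped {len(missing)} classifier gene(s) absent from the unknown: {missing}"
        )
        model = ReferenceModel(
            node_id=model.node_id,
            classifier_genes=genes,
            ref_matrix=model.ref_matrix.subset_genes(genes),
            child_labels=model.child_labels,
            sample_child=model.sample_child,
        )
    vec = unknown.reindex(model.classifier_genes).to_numpy(dtype=np.float64)
    if not np.isfinite(vec).all():
        raise CoverageError(
            f"node {model.node_id!r}: unknown sample has non-finite classifier values"
        )
    return model, vec, notes


def _node_statistics(
    projection: PCAProjection,
    model: ReferenceModel,
    unknown_scores: np.ndarray,
    sigma_ddof: int,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-child weighted distance of the unknown to the child centroid, and
    sigma of the child's own sample-to-centroid distances."""
    w = projection.weights
    distances: dict[str, float] = {}
    sigmas: dict[str, float] = {}
    row_of = {s: i for i, s in enumerate(projection.sample_ids)}
    for child in model.child_labels:
        ids = model.child_sample_ids(child)
        rows = projection.scores[[row_of[s] for s in ids], :]
        c = centroid(rows)
        distances[child] = weighted_distance(unknown_scores, c, w)
        child_d = np.array([weighted_distance(r, c, w) for r in rows])
        sigmas[child] = float(child_d.std(ddof=sigma_ddof))
    return distances, sigmas


def classify_node(
    model: ReferenceModel,
    unknown: pd.Series,
    mode: str = "merge",
    n_components: int | str = "all",
    sigma_ddof: int = 0,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> NodeResult:
    """Assign the unknown to one child of a single decision node.

    mode "merge" refits the PCA on reference + unknown (the published
    procedure); "project" projects the unknown onto a basis fit on the
    reference alone, so the reference geometry never depends on the unknown.
    """
    if mode not in ("merge", "project"):
        raise ParameterError(f"mode must be 'merge' or 'project', got {mode!r}")
    model, vec, notes = _align_unknown(model, unknown, coverage_threshold)

    if mode == "merge":
        projection = merge_and_project(
            model.ref_matrix, vec, n_components=n_components, unknown_id=_UNKNOWN_ID
        )
        unknown_scores = projection.scores[-1]
        ref_projection = projection
    else:
        projection = fit_pca(model.ref_matrix, n_components=n_components)
        unknown_scores = (vec - projection.center) @ projection.basis
        ref_projection = projection

    distances, sigmas = _node_statistics(ref_projection, model, unknown_scores, sigma_ddof)
    probabilities = membership_probabilities(distances)
    relative_distances = {
        child: relative_distance(distances[child], sigmas[child])
        for child in model.child_labels
    }

    dmin = min(distances.values())
    ties = [c for c in model.child_labels if distances[c] == dmin]
    assigned = ties[0]
    if len(ties) > 1:
        notes.append(
            f"distance tie between {ties}; assigned first declared child {assigned!r}"
        )

    k3 = min(3, ref_projection.scores.shape[1])
    row_of = {s: i for i, s in enumerate(ref_projection.sample_ids)}
    pc3_reference = {
        s: ref_projection.scores[row_of[s], :k3].tolist()
        for s in model.ref_matrix.sample_ids
    }
    return NodeResult(
        node_id=model.node_id,
        distances=distances,
        probabilities=probabilities,
        relative_distances=relative_distances,
        assigned_child=assigned,
        weights=ref_projection.weights,
        pc3_unknown=unknown_scores[:k3].tolist(),
        pc3_reference=pc3_reference,
        child_of_sample=dict(model.sample_child),
        warnings=notes,
    )


def classify_hierarchical(
    models: dict[str, ReferenceModel],
    hierarchy: SubtypeHierarchy,
    unknown: pd.Series,
    sample_id: str = "unknown",
    mode: str = "merge",
    n_components: int | str = "all",
    sigma_ddof: int = 0,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
) -> PredictionResult:
    """Descend from the root, assigning a child at each node, until a leaf.

    The outlier flag is raised if the assigned child's relative distance
    exceeds ``outlier_threshold`` at any level; the assignment itself is
    never suppressed.
    """
    node = hierarchy.root
    node_results: list[NodeResult] = []
    outlier = False
    while True:
        if node.node_id not in models:
            raise ParameterError(f"no reference model for hierarchy node {node.node_id!r}")
        result = classify_node(
            models[node.node_id],
            unknown,
            mode=mode,
            n_components=n_components,
            sigma_ddof=sigma_ddof,
            coverage_threshold=coverage_threshold,
        )
        node_results.append(result)
        if result.relative_distances[result.assigned_child] > outlier_threshold:
            outlier = True
        nxt = node.children[result.assigned_child]
        if nxt is None:
            final = result.assigned_child
            break
        node = nxt
    rule = f"r_D(assigned child) > {outlier_threshold:g} at any hierarchy level"
    return PredictionResult(
        sample_id=sample_id,
        node_results=node_results,
        final_subtype=final,
        outlier_flag=outlier,
        outlier_rule=rule,
    )
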