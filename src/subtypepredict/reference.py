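"""Per-node reference models built from a labeled cohort.

Each hierarchy node gets a ReferenceModel holding the raw classifier-gene
submatrix of the samples belonging to that node, plus each sample's child
label after roll-up.  In merge mode the PC-space centroids and distance
dispersions depend on the unknown being classified (the basis is refit on
the merged matrix), so they are recomputed per prediction from this raw
material; in project mode they can be computed once from a frozen basis.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import BuildError, CoverageError
from .hierarchy import SubtypeHierarchy
from .io import ExpressionMatrix, LabeledReference

logger = logging.getLogger(__name__)

#: default maximum tolerated fraction of absent classifier genes per node
DEFAULT_COVERAGE_THRESHOLD = 0.05


@dataclass
class ReferenceModel:
    """Reference material for one decision node."""

    node_id: str
    classifier_genes: list[str]
    ref_matrix: ExpressionMatrix  # classifier genes x node samples
    child_labels: list[str]  # declared child order (tie-break order)
    sample_child: dict[str, str]  # sample id -> child label at this node

    @property
    def n_samples(self) -> int:
        return self.ref_matrix.n_samples

    def child_sample_ids(self, child: str) -> list[str]:
        return [s for s in self.ref_matrix.sample_ids if self.sample_child[s] == child]


def centroid(scores: np.ndarray) -> np.ndarray:
    """Component-wise arithmetic mean of PC-score rows."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] < 1:
        raise BuildError("centroid requires at least one score row")
    return scores.mean(axis=0)


def resolve_coverage(
    classifier_genes: list[str],
    available: set[str],
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    context: str = "input",
) -> list[str]:
    """Apply the missing-gene policy: genes absent from ``available`` are
    dropped if they make up less than ``coverage_threshold`` of the list,
    otherwise a CoverageError lists them."""
    missing = [g for g in classifier_genes if g not in available]
    if not missing:
        return list(classifier_genes)
    frac = len(missing) / len(classifier_genes)
    if frac >= coverage_threshold:
        raise CoverageError(
            f"{context}: {len(missing)}/{len(classifier_genes)} classifier genes "
            f"missing ({frac:.1%} >= {coverage_threshold:.1%}): {missing[:10]}"
        )
    msg = (
        f"{context}: dropping {len(missing)} absent classifier gene(s) "
        f"({frac:.1%} < {coverage_threshold:.1%}): {missing}"
    )
    logger.warning(msg)
    warnings.warn(msg, stacklevel=2)
    return [g for g in classifier_genes if g in available]


def build_reference(
    reference: LabeledReference,
    hierarchy: SubtypeHierarchy,
    classifier_sets: dict[str, list[str]],
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> dict[str, ReferenceModel]:
    """Build one ReferenceModel per hierarchy node.

    Node sample sets nest: a node's samples are exactly those whose leaf
    label rolls up to one of its child labels.  Every child must keep at
    least 2 samples so its distance dispersion sigma is defined.
    """
    reference.validate_against(hierarchy)
    available = set(reference.matrix.gene_ids)
    models: dict[str, ReferenceModel] = {}
    for node in hierarchy.nodes():
        if node.node_id not in classifier_sets:
            raise BuildError(f"no classifier gene list for hierarchy node {node.node_id!r}")
        genes = resolve_coverage(
            classifier_sets[node.node_id],
            available,
            coverage_threshold,
            context=f"node {node.node_id!r} vs reference matrix",
        )
        if len(genes) < 1:
            raise BuildError(f"node {node.node_id!r} has no usable classifier genes")

        sample_child: dict[str, str] = {}
        for sample in reference.matrix.sample_ids:
            child = hierarchy.child_label_at(node.node_id, reference.labels[sample])
            if child is not None:
                sample_child[sample] = child
        for child in node.child_labels():
            n_child = sum(1 for c in sample_child.values() if c == child)
            if n_child < 2:
                raise BuildError(
                    f"child {child!r} of node {node.node_id!r} has {n_child} reference "
                    "sample(s); at least 2 are required to estimate sigma"
                )
        sub = reference.matrix.subset_genes(genes).subset_samples(list(sample_child))
        models[node.node_id] = ReferenceModel(
            node_id=node.node_id,
            classifier_genes=genes,
            ref_matrix=sub,
            child_labels=node.child_labels(),
            sample_child=sample_child,
        )
    return models


# ---------------------------------------------------------------------------
# Reference bundle (hierarchy + classifier sets + labeled matrix) as JSON
# ---------------------------------------------------------------------------

def save_bundle(
    path,
    reference: LabeledReference,
    hierarchy: SubtypeHierarchy,
    classifier_sets: dict[str, list[str]],
) -> None:
    """Serialize everything a prediction needs into one JSON file."""
    payload = {
        "format": "subtypepredict-reference-bundle",
        "version": 1,
        "hierarchy": hierarchy.to_dict(),
        "classifier_sets": classifier_sets,
        "matrix": {
            "gene_ids": reference.matrix.gene_ids,
            "sample_ids": reference.matrix.sample_ids,
            "values": reference.matrix.values.tolist(),
        },
        "labels": reference.labels,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)
        fh.write("\n")


def load_bundle(path) -> tuple[LabeledReference, SubtypeHierarchy, dict[str, list[str]]]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "subtypepredict-reference-bundle":
        raise BuildError(f"{path}: not a reference bundle")
    hierarchy = SubtypeHierarchy.from_dict(payload["hierarchy"])
    m = payload["matrix"]
    matrix = ExpressionMatrix(m["gene_ids"], m["sample_ids"], np.array(m["values"]))
    reference = LabeledReference(matrix, dict(payload["labels"]))
    reference.validate_against(hierarchy)
    return reference, hierarchy, {k: list(v) for k, v in payload["classifier_sets"].items()}
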