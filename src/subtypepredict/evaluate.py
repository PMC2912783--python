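"""Per-level assignment accuracy under train->test and leave-one-out protocols.

Accuracy is reported per hierarchy node and conditioned on the true parent
path: a sample whose true leaf is OA counts toward the root node and the O
node, never toward the G node.  Each evaluated sample is classified AT the
node in question (against that node's reference model), which isolates
per-level accuracy from upstream mistakes, mirroring how per-level accuracy
rows are usually tabulated.  Full root-to-leaf descent is available
separately via ``classify_hierarchical``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import BuildError, ParameterError
from .estimators import HierarchicalSubtypeClassifier
from .hierarchy import SubtypeHierarchy
from .io import LabeledReference


@dataclass
class NodeEvaluation:
    node_id: str
    confusion: dict[str, dict[str, int]]  # true child -> predicted child -> count
    n: int

    @property
    def accuracy(self) -> float:
        correct = sum(self.confusion.get(c, {}).get(c, 0) for c in self.confusion)
        return correct / self.n if self.n else float("nan")


@dataclass
class EvaluationReport:
    protocol: str  # "train_test" | "loo"
    per_node: dict[str, NodeEvaluation]
    n_evaluated: int

    def accuracies(self) -> dict[str, float]:
        return {k: v.accuracy for k, v in self.per_node.items()}

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "n_evaluated": self.n_evaluated,
            "per_node": {
                k: {"accuracy": v.accuracy, "n": v.n, "confusion": v.confusion}
                for k, v in self.per_node.items()
            },
        }

    def to_markdown(self) -> str:
        lines = [
            f"# Subtype assignment accuracy ({self.protocol})",
            "",
            f"Samples evaluated: {self.n_evaluated}",
            "",
            "| node | n | accuracy |",
            "|------|---|----------|",
        ]
        for node_id, ev in self.per_node.items():
            lines.append(f"| {node_id} | {ev.n} | {ev.accuracy:.3f} |")
        return "\n".join(lines) + "\n"


def _empty_confusion(children: list[str]) -> dict[str, dict[str, int]]:
    return {t: {p: 0 for p in children} for t in children}


def _score_cohort(
    clf: HierarchicalSubtypeClassifier,
    cohort: LabeledReference,
    sample_ids: list[str],
    protocol: str,
) -> EvaluationReport:
    hierarchy = clf.hierarchy_
    per_node = {
        node.node_id: NodeEvaluation(node.node_id, _empty_confusion(node.child_labels()), 0)
        for node in hierarchy.nodes()
    }
    for sample in sample_ids:
        profile = cohort.matrix.sample_vector(sample)
        true_leaf = cohort.labels[sample]
        for node, true_child in hierarchy.leaf_path(true_leaf):
            predicted = clf.node_result(node.node_id, profile).assigned_child
            ev = per_node[node.node_id]
            ev.confusion[true_child][predicted] += 1
            ev.n += 1
    return EvaluationReport(protocol, per_node, len(sample_ids))


def evaluate_train_test(
    train: LabeledReference,
    test: LabeledReference,
    hierarchy: SubtypeHierarchy,
    classifier_sets: dict[str, list[str]],
    **options,
) -> EvaluationReport:
    """Classify every test sample against a reference built from the training
    cohort; accuracy per node over test samples whose true path traverses it."""
    if test.matrix.n_samples == 0:
        raise ParameterError("test cohort is empty")
    clf = HierarchicalSubtypeClassifier.from_reference(
        train, hierarchy, classifier_sets, **options
    )
    return _score_cohort(clf, test, list(test.matrix.sample_ids), "train_test")


def evaluate_loo(
    reference: LabeledReference,
    hierarchy: SubtypeHierarchy,
    classifier_sets: dict[str, list[str]],
    **options,
) -> EvaluationReport:
    """Leave-one-out over the reference cohort: each held-out sample is
    classified against models rebuilt without it, so it never contributes to
    the basis, centroids or sigma of its own prediction."""
    leaves = {}
    for sample in reference.matrix.sample_ids:
        leaves.setdefault(reference.labels[sample], []).append(sample)
    for leaf, members in leaves.items():
        if len(members) < 3:
            raise BuildError(
                f"leaf {leaf!r} has {len(members)} samples; leave-one-out needs >= 3 "
                "so every child keeps >= 2 after holdout"
            )

    per_node: dict[str, NodeEvaluation] = {
        node.node_id: NodeEvaluation(node.node_id, _empty_confusion(node.child_labels()), 0)
        for node in hierarchy.nodes()
    }
    all_ids = list(reference.matrix.sample_ids)
    for sample in all_ids:
        keep = [s for s in all_ids if s != sample]
        held_out = LabeledReference(
            reference.matrix.subset_samples(keep),
            {s: reference.labels[s] for s in keep},
        )
        clf = HierarchicalSubtypeClassifier.from_reference(
            held_out, hierarchy, classifier_sets, **options
        )
        profile = reference.matrix.sample_vector(sample)
        for node, true_child in hierarchy.leaf_path(reference.labels[sample]):
            predicted = clf.node_result(node.node_id, profile).assigned_child
            ev = per_node[node.node_id]
            ev.confusion[true_child][predicted] += 1
            ev.n += 1
    return EvaluationReport("loo", per_node, len(all_ids))
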