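"""Seeded synthetic cohorts with nested Gaussian cluster structure.

These fixtures emulate, structurally, a labeled reference cohort of tumor
expression profiles: per hierarchy node a disjoint set of classifier genes,
each child subtype Gaussian around a child-specific mean on those genes, plus
background genes of pure noise.  They exist to exercise the classification
math under known ground truth — no attempt is made to imitate microarray
heteroskedasticity, probe effects or batch structure.

Geometry of the signal: a node's classifier genes are partitioned round-robin
into one block per child; a child's mean is ``delta_mu`` on its own block and
0 elsewhere, so any two child means differ by ``delta_mu`` per differing gene
and their Euclidean separation in gene space is ``delta_mu * sqrt(2 g / m)``
for g genes and m children.  Samples not under a node (e.g. G samples on the
O node's genes) are pure noise around 0 there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LabelError, ParameterError
from .hierarchy import SubtypeHierarchy
from .io import ExpressionMatrix, LabeledReference


@dataclass
class SimulationSpec:
    """Study conditions for a synthetic cohort.

    delta_mu and sigma_e are in expression units (the same unitless scale as
    normalized intensities); delta_mu is the per-gene between-child mean
    shift and sigma_e the within-child noise standard deviation.
    """

    hierarchy: SubtypeHierarchy = field(default_factory=SubtypeHierarchy.default_glioma)
    n_per_leaf: int = 20
    genes_per_node: int = 30
    delta_mu: float = 4.0
    sigma_e: float = 1.0
    n_background: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_leaf < 2:
            raise ParameterError("n_per_leaf must be >= 2")
        if self.genes_per_node < 2:
            raise ParameterError("genes_per_node must be >= 2")
        max_children = max(len(n.children) for n in self.hierarchy.nodes())
        if self.genes_per_node < max_children:
            raise ParameterError(
                f"genes_per_node={self.genes_per_node} < {max_children} children: "
                "some child would have no discriminating gene"
            )
        if self.delta_mu < 0:
            raise ParameterError("delta_mu must be >= 0")
        if self.sigma_e <= 0:
            raise ParameterError("sigma_e must be > 0")
        if self.n_background < 0:
            raise ParameterError("n_background must be >= 0")


def _classifier_sets(spec: SimulationSpec) -> dict[str, list[str]]:
    return {
        node.node_id: [
            f"{node.node_id}_clf_{j + 1:03d}" for j in range(spec.genes_per_node)
        ]
        for node in spec.hierarchy.nodes()
    }


def _background_genes(spec: SimulationSpec) -> list[str]:
    return [f"bg_{j + 1:03d}" for j in range(spec.n_background)]


def _child_block(spec: SimulationSpec, node_id: str) -> dict[str, np.ndarray]:
    """Per-child mean vector over one node's classifier genes (round-robin
    block assignment)."""
    node = spec.hierarchy.node(node_id)
    children = node.child_labels()
    g, m = spec.genes_per_node, len(children)
    means = {}
    for j, child in enumerate(children):
        mu = np.zeros(g)
        mu[j::m] = spec.delta_mu
        means[child] = mu
    return means


def leaf_mean_profile(spec: SimulationSpec, leaf: str) -> pd.Series:
    """The exact generative mean expression of a leaf subtype over all genes
    (classifier and background); useful as a centroid-planted probe."""
    if leaf not in spec.hierarchy.leaves():
        raise LabelError(f"{leaf!r} is not a leaf of the hierarchy")
    sets = _classifier_sets(spec)
    parts: list[pd.Series] = []
    path = {node.node_id: label for node, label in spec.hierarchy.leaf_path(leaf)}
    for node in spec.hierarchy.nodes():
        genes = sets[node.node_id]
        if node.node_id in path:
            mu = _child_block(spec, node.node_id)[path[node.node_id]]
        else:
            mu = np.zeros(len(genes))
        parts.append(pd.Series(mu, index=genes))
    parts.append(pd.Series(0.0, index=_background_genes(spec)))
    out = pd.concat(parts)
    out.name = f"mean_{leaf}"
    return out


def simulate_cohort(spec: SimulationSpec) -> tuple[LabeledReference, dict[str, list[str]]]:
    """Generate a labeled reference cohort and its per-node classifier sets.

    Fully reproducible from ``spec.seed``: the same spec yields bit-identical
    matrices.
    """
    rng = np.random.default_rng(spec.seed)
    leaves = spec.hierarchy.leaves()
    sample_ids = [f"{leaf}_{k + 1:03d}" for leaf in leaves for k in range(spec.n_per_leaf)]
    labels = {f"{leaf}_{k + 1:03d}": leaf for leaf in leaves for k in range(spec.n_per_leaf)}

    mean_cols = np.column_stack(
        [leaf_mean_profile(spec, labels[s]).to_numpy() for s in sample_ids]
    )
    gene_ids = list(leaf_mean_profile(spec, leaves[0]).index)
    noise = rng.normal(0.0, spec.sigma_e, size=mean_cols.shape)
    matrix = ExpressionMatrix(gene_ids, sample_ids, mean_cols + noise)
    return LabeledReference(matrix, labels), _classifier_sets(spec)


def make_unknown(
    spec: SimulationSpec,
    leaf_label: str,
    displacement: float = 0.0,
    seed: int | None = None,
) -> pd.Series:
    """Draw one unknown profile from a leaf's generative distribution.

    ``displacement`` shifts the probe away from every node's centroid: for
    each hierarchy node, a random unit direction within that node's
    classifier genes is scaled by ``displacement * sigma_e`` and added, so
    the probe ends up the stated multiple of sigma_e away from where its
    subtype lives at every level of the hierarchy.

    The draw is reproducible: ``seed`` defaults to a value derived from
    ``spec.seed`` and the leaf, distinct from the cohort's own stream.
    """
    leaves = spec.hierarchy.leaves()
    if leaf_label not in leaves:
        raise LabelError(f"{leaf_label!r} is not a leaf of the hierarchy")
    if seed is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 1 + leaves.index(leaf_label)])
        )
    else:
        rng = np.random.default_rng(seed)
    mean = leaf_mean_profile(spec, leaf_label)
    values = mean.to_numpy() + rng.normal(0.0, spec.sigma_e, size=len(mean))
    profile = pd.Series(values, index=mean.index, name=f"unknown_{leaf_label}")
    if displacement != 0.0:
        for node_id, genes in _classifier_sets(spec).items():
            direction = rng.normal(size=len(genes))
            direction /= np.linalg.norm(direction)
            profile[genes] += displacement * spec.sigma_e * direction
    return profile
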