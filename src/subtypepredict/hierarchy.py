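"""Nested subtype hierarchies.

A classification hierarchy is a rooted tree of decision nodes.  Each node
discriminates between >= 2 child labels; a child label either terminates in a
leaf subtype or leads to a further decision node.  The default instance is the
two-level glioma stratification: root {O, G}; O -> {OA, OB};
G -> {GA1, GA2, GB1, GB2}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .errors import LabelError, ParameterError


@dataclass
class HierarchyNode:
    """One decision node: maps each child subtype label to a deeper node or,
    for a leaf label, to ``None``."""

    node_id: str
    children: dict[str, "HierarchyNode | None"] = field(default_factory=dict)

    def child_labels(self) -> list[str]:
        return list(self.children)


class SubtypeHierarchy:
    """Rooted tree of classification nodes with unique node ids and leaf labels."""

    def __init__(self, root: HierarchyNode):
        self.root = root
        self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def default_glioma(cls) -> "SubtypeHierarchy":
        """The six-subtype nested glioma hierarchy."""
        o_node = HierarchyNode("O", {"OA": None, "OB": None})
        g_node = HierarchyNode("G", {"GA1": None, "GA2": None, "GB1": None, "GB2": None})
        root = HierarchyNode("root", {"O": o_node, "G": g_node})
        return cls(root)

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeHierarchy":
        def build(spec: dict) -> HierarchyNode:
            children: dict[str, HierarchyNode | None] = {}
            for label, sub in spec.get("children", {}).items():
                children[label] = None if sub is None else build(sub)
            return HierarchyNode(spec["node_id"], children)

        return cls(build(d))

    def to_dict(self) -> dict:
        def dump(node: HierarchyNode) -> dict:
            return {
                "node_id": node.node_id,
                "children": {
                    label: (None if sub is None else dump(sub))
                    for label, sub in node.children.items()
                },
            }

        return dump(self.root)

    @classmethod
    def from_json(cls, path) -> "SubtypeHierarchy":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    # -- traversal ----------------------------------------------------------

    def nodes(self) -> list[HierarchyNode]:
        """All decision nodes, root first, in depth-first declaration order."""
        out: list[HierarchyNode] = []

        def walk(node: HierarchyNode) -> None:
            out.append(node)
            for sub in node.children.values():
                if sub is not None:
                    walk(sub)

        walk(self.root)
        return out

    def node(self, node_id: str) -> HierarchyNode:
        for n in self.nodes():
            if n.node_id == node_id:
                return n
        raise LabelError(f"unknown hierarchy node {node_id!r}")

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: HierarchyNode) -> None:
            for label, sub in node.children.items():
                if sub is None:
                    out.append(label)
                else:
                    walk(sub)

        walk(self.root)
        return out

    def leaf_path(self, leaf: str) -> list[tuple[HierarchyNode, str]]:
        """Root-to-leaf decision path as (node, child label chosen) pairs."""

        def search(node: HierarchyNode) -> list[tuple[HierarchyNode, str]] | None:
            for label, sub in node.children.items():
                if sub is None:
                    if label == leaf:
                        return [(node, label)]
                else:
                    deeper = search(sub)
                    if deeper is not None:
                        return [(node, label)] + deeper
            return None

        path = search(self.root)
        if path is None:
            raise LabelError(
                f"{leaf!r} is not a leaf subtype; valid leaves: {', '.join(self.leaves())}"
            )
        return path

    def child_label_at(self, node_id: str, leaf: str) -> str | None:
        """The child label a sample with leaf subtype ``leaf`` rolls up to at
        node ``node_id``, or None if the leaf's path avoids that node."""
        for node, label in self.leaf_path(leaf):
            if node.node_id == node_id:
                return label
        return None

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        seen_nodes: set[str] = set()
        seen_leaves: set[str] = set()

        def walk(node: HierarchyNode) -> None:
            if node.node_id in seen_nodes:
                raise ParameterError(f"duplicate node id {node.node_id!r}")
            seen_nodes.add(node.node_id)
            if len(node.children) < 2:
                raise ParameterError(
                    f"hierarchy node {node.node_id!r} has {len(node.children)} "
                    "child labels; every node needs at least 2"
                )
            for label, sub in node.children.items():
                if sub is None:
                    if label in seen_leaves:
                        raise ParameterError(f"leaf label {label!r} reachable twice")
                    seen_leaves.add(label)
                else:
                    walk(sub)

        walk(self.root)
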