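"""Prediction reports: canonical JSON, plain text, and plot-ready PC coordinates.

Every report embeds full provenance for any number it prints: the tool
version, an echo of the run configuration, and SHA-256 digests of the input
files.  Reports carry no timestamps, so identical inputs and configuration
produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .classify import PredictionResult
from .errors import FormatError


@dataclass
class RunConfig:
    """Run-level configuration echoed into every report."""

    mode: str = "merge"
    n_components: int | str = "all"
    outlier_threshold: float = 3.0
    sigma_divisor: str = "n"
    coverage_threshold: float = 0.05
    seed: int | None = None
    paths: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_report(
    result: PredictionResult,
    config: RunConfig | None = None,
    input_digests: dict[str, str] | None = None,
) -> dict:
    """Assemble the canonical JSON-serializable report for one prediction."""
    config = config or RunConfig()
    levels = []
    for nr in result.node_results:
        levels.append(
            {
                "node_id": nr.node_id,
                "assigned_child": nr.assigned_child,
                "probabilities": {k: float(v) for k, v in nr.probabilities.items()},
                "distances": {k: float(v) for k, v in nr.distances.items()},
                "relative_distances": {
                    k: float(v) for k, v in nr.relative_distances.items()
                },
                "pc3_unknown": [float(v) for v in nr.pc3_unknown],
                "pc3_reference": {
                    s: [float(v) for v in coords] for s, coords in nr.pc3_reference.items()
                },
                "reference_children": dict(nr.child_of_sample),
                "warnings": list(nr.warnings),
            }
        )
    return {
        "format": "subtypepredict-report",
        "version": __version__,
        "config": config.to_dict(),
        "input_digests": dict(input_digests or {}),
        "sample_id": result.sample_id,
        "final_subtype": result.final_subtype,
        "outlier_flag": bool(result.outlier_flag),
        "outlier_rule": result.outlier_rule,
        "levels": levels,
    }


def write_report_json(report: dict, path) -> None:
    validate_report(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def render_text(report: dict) -> str:
    """Human-readable summary mirroring the per-level content of the JSON."""
    lines = [
        f"subtypepredict v{report['version']} prediction report",
        f"sample: {report['sample_id']}",
        f"final subtype: {report['final_subtype']}",
        f"outlier: {'YES' if report['outlier_flag'] else 'no'}  "
        f"(rule: {report['outlier_rule']})",
        "",
    ]
    for level in report["levels"]:
        lines.append(f"level {level['node_id']}: assigned {level['assigned_child']}")
        for child in level["probabilities"]:
            lines.append(
                f"  {child:>6}: p={level['probabilities'][child]:.4f}  "
                f"d={level['distances'][child]:.4f}  "
                f"r_D={level['relative_distances'][child]:.3f}"
            )
        for w in level["warnings"]:
            lines.append(f"  warning: {w}")
        lines.append("")
    return "\n".join(lines)


def write_report_text(report: dict, path) -> None:
    Path(path).write_text(render_text(report))


def write_pc_coordinates(report: dict, path) -> None:
    """Plot-ready TSV of first-3-PC coordinates: one row per reference sample
    and per unknown, per hierarchy level."""
    with open(path, "w") as fh:
        fh.write("node_id\tsample_id\trole\tchild\tPC1\tPC2\tPC3\n")
        for level in report["levels"]:
            def fmt(coords: list[float]) -> str:
                padded = list(coords) + [float("nan")] * (3 - len(coords))
                return "\t".join(repr(float(c)) for c in padded[:3])

            for s, coords in level["pc3_reference"].items():
                child = level["reference_children"].get(s, "")
                fh.write(f"{level['node_id']}\t{s}\treference\t{child}\t{fmt(coords)}\n")
            fh.write(
                f"{level['node_id']}\t{report['sample_id']}\tunknown\t"
                f"{level['assigned_child']}\t{fmt(level['pc3_unknown'])}\n"
            )


# ---------------------------------------------------------------------------
# Report schema (documented in docs/report.schema.json) + structural checker
# ---------------------------------------------------------------------------

REPORT_SCHEMA: dict = {
    "type": "object",
    "required": [
        "format",
        "version",
        "config",
        "input_digests",
        "sample_id",
        "final_subtype",
        "outlier_flag",
        "outlier_rule",
        "levels",
    ],
    "properties": {
        "format": {"type": "string", "const": "subtypepredict-report"},
        "version": {"type": "string"},
        "config": {"type": "object"},
        "input_digests": {"type": "object"},
        "sample_id": {"type": "string"},
        "final_subtype": {"type": "string"},
        "outlier_flag": {"type": "boolean"},
        "outlier_rule": {"type": "string"},
        "levels": {
            "type": "array",
            "items": {
                "type": "object",
                "required": [
                    "node_id",
                    "assigned_child",
                    "probabilities",
                    "distances",
                    "relative_distances",
                    "pc3_unknown",
                    "pc3_reference",
                    "reference_children",
                    "warnings",
                ],
                "properties": {
                    "node_id": {"type": "string"},
                    "assigned_child": {"type": "string"},
                    "probabilities": {"type": "object", "values": {"type": "number"}},
                    "distances": {"type": "object", "values": {"type": "number"}},
                    "relative_distances": {"type": "object", "values": {"type": "number"}},
                    "pc3_unknown": {"type": "array", "items": {"type": "number"}},
                    "pc3_reference": {"type": "object"},
                    "reference_children": {"type": "object"},
                    "warnings": {"type": "array", "items": {"type": "string"}},
                },
            },
        },
    },
}

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "boolean": bool,
}


def _check(obj, schema: dict, where: str) -> None:
    expected = schema.get("type")
    if expected:
        if expected == "boolean":
            ok = isinstance(obj, bool)
        elif expected == "number":
            ok = isinstance(obj, (int, float)) and not isinstance(obj, bool)
        else:
            ok = isinstance(obj, _TYPES[expected]) and not isinstance(obj, bool)
        if not ok:
            raise FormatError(
                f"report{where}: expected {expected}, got {type(obj).__name__}"
            )
    if "const" in schema and obj != schema["const"]:
        raise FormatError(f"report{where}: expected {schema['const']!r}, got {obj!r}")
    for key in schema.get("required", []):
        if key not in obj:
            raise FormatError(f"report{where}: missing required key {key!r}")
    if expected == "object":
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check(obj[key], sub, f"{where}.{key}")
        values_schema = schema.get("values")
        if values_schema:
            for key, val in obj.items():
                _check(val, values_schema, f"{where}.{key}")
    if expected == "array" and "items" in schema:
        for i, item in enumerate(obj):
            _check(item, schema["items"], f"{where}[{i}]")


def validate_report(report: dict) -> None:
    """Check a report against the shipped schema (types, required keys,
    constants); raises FormatError on the first violation."""
    _check(report, REPORT_SCHEMA, "")
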