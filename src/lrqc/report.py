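"""Consolidated per-dataset metrics report with QC flags.

All rates are stored as fractions in the JSON report; percentage rendering
is left to the human-readable views. The report carries every parameter
the run resolved (no silent defaults) plus a schema_version, and a small
shipped schema lets consumers check structure without extra dependencies.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import asdict, dataclass, field

from . import __version__
from .assembly_stats import NxStats
from .evenness import EvennessResult
from .hic_qc import HicMetrics
from .linked_qc import LinkedMetrics

SCHEMA_VERSION = "1.0"

__all__ = ["MetricsReport", "assemble_report", "load_schema", "validate_report", "SCHEMA_VERSION"]


def _hic_to_dict(m: HicMetrics) -> dict:
    d = {
        "n_pairs": m.n_pairs,
        "n_unmapped": m.n_unmapped,
        "n_duplicate": m.n_duplicate,
        "n_inter": m.n_inter,
        "n_intra": m.n_intra,
        "unmapped_rate": m.unmapped_rate,
        "duplication_rate": m.duplication_rate,
        "ici_rate": m.ici_rate,
        "total_accessibility": round(m.total_accessibility, 3),
        "ici_conditional_rate": None if m.ici is None else m.ici.rate,
        "association": None,
    }
    if m.association is not None:
        d["association"] = {
            "exponent": m.association.exponent,
            "r_squared": m.association.r_squared,
            "d_min": m.association.d_min,
            "d_max": m.association.d_max,
            "n_bins": m.association.n_bins,
        }
    return d


def _linked_to_dict(m: LinkedMetrics) -> dict:
    return {
        "n_reads": m.n_reads,
        "n_read_pairs": m.n_read_pairs,
        "unmapped_rate": m.unmapped_rate,
        "duplication_rate": m.duplication_rate,
        "total_accessibility": round(m.total_accessibility, 3),
        "molecule_n50": m.molecule_n50,
        "reads_per_molecule_n50_ge3": m.reads_per_molecule_n50_ge3,
        "reads_per_molecule_n50_ge5": m.reads_per_molecule_n50_ge5,
        "clustered_read_pct": m.clustered_read_pct,
        "collision_rate": m.collision_rate,
    }


def _evenness_to_dict(e: EvennessResult) -> dict:
    return {
        "mean": e.mean,
        "variance": e.variance,
        "unevenness": round(e.unevenness, 1),
        "unevenness_exact": e.unevenness,
        "n_sites": e.n_sites,
        "degenerate": e.degenerate,
    }


@dataclass
class MetricsReport:
    """Dataset-level bundle mirroring the published QC table structure."""

    dataset_id: str
    platform: str = "unknown"
    parameters: dict = field(default_factory=dict)
    hic: dict | None = None
    linked: dict | None = None
    evenness: dict | None = None
    assembly: dict | None = None
    qc: dict = field(default_factory=dict)
    tool_version: str = __version__
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "MetricsReport":
        return cls(**data)


def assemble_report(
    dataset_id: str,
    platform: str = "unknown",
    parameters: dict | None = None,
    hic: HicMetrics | None = None,
    linked: LinkedMetrics | None = None,
    evenness: EvennessResult | None = None,
    assembly: NxStats | None = None,
    unevenness_threshold: float | None = None,
) -> MetricsReport:
    """Bundle computed metric objects into one report with QC flags."""
    qc: dict = {}
    if hic is not None:
        qc["ici_pass"] = hic.qc_ici_pass
        qc["powerlaw_fit_ok"] = hic.qc_powerlaw_ok
        qc["accessibility"] = round(hic.total_accessibility, 3)
    if linked is not None:
        qc["accessibility"] = round(linked.total_accessibility, 3)
    if evenness is not None:
        qc["unevenness"] = round(evenness.unevenness, 1)
        if unevenness_threshold is not None:
            qc["unevenness_pass"] = evenness.unevenness <= unevenness_threshold
    return MetricsReport(
        dataset_id=dataset_id,
        platform=platform,
        parameters=dict(parameters or {}),
        hic=None if hic is None else _hic_to_dict(hic),
        linked=None if linked is None else _linked_to_dict(linked),
        evenness=None if evenness is None else _evenness_to_dict(evenness),
        assembly=None if assembly is None else assembly.to_dict(),
        qc=qc,
    )


def load_schema() -> dict:
    text = importlib.resources.files("lrqc").joinpath("report_schema.json").read_text()
    return json.loads(text)


_TYPES = {
    "string": str,
    "number": (int, float),
    "integer": int,
    "boolean": bool,
    "object": dict,
    "array": list,
    "null": type(None),
}


def validate_report(data: dict, schema: dict | None = None, _path: str = "report") -> None:
    """Check a report dict against the shipped schema (required keys and
    primitive types; nullable via a type list). Raises ValueError on the
    first violation."""
    schema = load_schema() if schema is None else schema
    for key in schema.get("required", []):
        if key not in data:
            raise ValueError(f"{_path}: missing required field {key!r}")
    for key, spec in schema.get("properties", {}).items():
        if key not in data:
            continue
        value = data[key]
        types = spec.get("type", [])
        if isinstance(types, str):
            types = [types]
        if types:
            allowed = tuple(t for name in types for t in (
                _TYPES[name] if isinstance(_TYPES[name], tuple) else (_TYPES[name],)
            ))
            if not isinstance(value, allowed) or (
                isinstance(value, bool) and bool not in allowed
            ):
                raise ValueError(
                    f"{_path}.{key}: expected {types}, got {type(value).__name__}"
                )
        if isinstance(value, dict) and "properties" in spec:
            validate_report(value, spec, f"{_path}.{key}")
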