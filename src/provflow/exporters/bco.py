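"""BioCompute Object (IEEE 2791-2020) export.

A BCO carries full provenance for a stored workflow: contributor and
license metadata from every component, one pipeline step per workflow
step (numbered from 0, in workflow order), the stacked story sentences
as the usability domain, prompt configurations in the parametric domain,
and result data URIs in the io domain.

The integrity ``etag`` is the SHA-256 hex digest of the canonical
serialization of the document with the etag field removed, so any
recipient can recompute and verify it.
"""

from __future__ import annotations

from typing import Sequence

from .. import jsonschema_lite
from ..canonical import content_hash
from ..registry import Registry
from ..store import Store
from .ieee2791_schema_synthetic import IEEE2791_SCHEMA_SYNTHETIC
from .report import build_report

__all__ = ["export_bco", "compute_etag", "validate_bco"]

SPEC_VERSION = "https://w3id.org/ieee/ieee-2791-schema/2791object.json"
_EPOCH = "1970-01-01T00:00:00+00:00"


def compute_etag(document: dict) -> str:
    body = {k: v for k, v in document.items() if k != "etag"}
    return content_hash("bco", body)


def validate_bco(document: dict) -> list[str]:
    """Structural validation against the bundled 2791 schema rendering."""
    return jsonschema_lite.validate(document, IEEE2791_SCHEMA_SYNTHETIC)


def export_bco(
    registry: Registry,
    store: Store,
    tail: str,
    authors: Sequence[str] = (),
    name: str = "provflow workflow",
) -> dict:
    """Build the IEEE 2791 document for the workflow ending at *tail*.

    *authors* are recorded as createdBy contributors alongside the
    authors of every component used.  Timestamps come from stored result
    records (the latest execution), so exporting the same executed
    workflow twice is byte-identical.
    """
    chain = store.resolve_list(tail)
    if not chain:
        raise ValueError("cannot export an empty workflow")
    report = build_report(registry, store, tail)

    contributors: list[dict] = []
    seen: set[str] = set()
    for person in authors:
        if person not in seen:
            seen.add(person)
            contributors.append({"name": person, "contribution": ["createdBy"]})
    timestamps: list[str] = []
    pipeline_steps = []
    parametric = []
    input_subdomain = []
    output_subdomain = []

    for number, pid in enumerate(chain):
        rec = store.get_process(pid)
        comp = registry.get_component(rec.component_id)
        for person in comp.authors:
            if person not in seen:
                seen.add(person)
                contributors.append({"name": person, "contribution": ["authoredBy"]})

        step_inputs = [
            {"uri": f"provflow://process/{dep}"} for dep in sorted(rec.inputs.values())
        ]
        result = store.get_result(pid)
        step_outputs = []
        if result is not None:
            timestamps.append(result.timestamp)
            if result.status == "ok" and result.data_id:
                uri = f"provflow://data/{result.data_id}"
                step_outputs.append({"uri": uri})
                output_subdomain.append(
                    {"mediatype": "application/json", "uri": {"uri": uri}}
                )
        pipeline_steps.append(
            {
                "step_number": number,
                "name": comp.label,
                "description": comp.description,
                "version": comp.version,
                "input_list": step_inputs,
                "output_list": step_outputs,
            }
        )
        if comp.kind == "prompt" and isinstance(rec.config, dict):
            input_subdomain.append({"uri": {"uri": f"provflow://process/{pid}#config"}})
            for param, value in sorted(rec.config.items()):
                parametric.append(
                    {"param": param, "value": str(value), "step": str(number)}
                )

    created = min(timestamps) if timestamps else _EPOCH
    modified = max(timestamps) if timestamps else _EPOCH
    licenses = sorted({registry.get_component(store.get_process(p).component_id).license
                       for p in chain})

    document = {
        "object_id": f"urn:provflow:bco:{tail}",
        "spec_version": SPEC_VERSION,
        "provenance_domain": {
            "name": name,
            "version": "1.0",
            "created": created,
            "modified": modified,
            "contributors": contributors,
            "license": ", ".join(licenses),
            "review": [],
        },
        "usability_domain": [s.story for s in report.steps],
        "description_domain": {
            "keywords": sorted(
                {store.get_process(p).component_id for p in chain}
            ),
            "pipeline_steps": pipeline_steps,
        },
        "execution_domain": {
            "script": [{"uri": {"uri": "provflow://cli/run"}}],
            "script_driver": "shell",
            "software_prerequisites": [
                {
                    "name": "provflow",
                    "version": "0.1.0",
                    "uri": {"uri": "https://pypi.org/project/provflow/"},
                }
            ],
            "external_data_endpoints": [],
            "environment_variables": {},
        },
        "io_domain": {
            "input_subdomain": input_subdomain,
            "output_subdomain": output_subdomain,
        },
        "parametric_domain": parametric,
        "error_domain": {"empirical_error": {}, "algorithmic_error": {}},
    }
    document["etag"] = compute_etag(document)
    return document
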