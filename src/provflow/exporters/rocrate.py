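"""Workflow RO-Crate export (RO-Crate 1.1 metadata, JSON-LD).

The crate packages the exported CWL workflow as its main entity together
with provenance metadata: one SoftwareApplication entity per component,
Person entities for authors (deduplicated — two components sharing an
author reference one entity), and license entities.  Written by hand as
plain JSON-LD following the Workflow RO-Crate profile structure.
"""

from __future__ import annotations

import json
from pathlib import Path
from ..registry import Registry
from ..store import Store
from .cwl import CWLBundle, export_cwl

__all__ = ["export_rocrate", "write_crate", "read_crate_graph", "check_crate"]

_PROFILE = "https://w3id.org/workflowhub/workflow-ro-crate/1.0"
_CONTEXT = "https://w3id.org/ro/crate/1.1/context"


def _person_id(name: str) -> str:
    return "#person-" + name.lower().replace(" ", "-")


def export_rocrate(
    registry: Registry,
    store: Store,
    tail: str,
    bundle: CWLBundle | None = None,
) -> dict:
    """Build the ro-crate-metadata.json document for the workflow at *tail*."""
    chain = store.resolve_list(tail)
    if not chain:
        raise ValueError("cannot export an empty workflow")
    if bundle is None:
        bundle = export_cwl(registry, store, tail)

    components = []
    seen_components = set()
    for pid in chain:
        cid = store.get_process(pid).component_id
        if cid not in seen_components:
            seen_components.add(cid)
            components.append(registry.get_component(cid))

    persons: dict[str, dict] = {}
    licenses: dict[str, dict] = {}
    component_entities = []
    for comp in components:
        for author in comp.authors:
            persons.setdefault(
                _person_id(author), {"@id": _person_id(author), "@type": "Person", "name": author}
            )
        lic_id = "#license-" + comp.license.lower().replace(" ", "-")
        licenses.setdefault(
            lic_id, {"@id": lic_id, "@type": "CreativeWork", "name": comp.license}
        )
        component_entities.append(
            {
                "@id": f"#component-{comp.id}",
                "@type": "SoftwareApplication",
                "name": comp.label,
                "description": comp.description,
                "softwareVersion": comp.version,
                "license": {"@id": lic_id},
                "author": [{"@id": _person_id(a)} for a in comp.authors],
            }
        )

    has_part = (
        [{"@id": "workflow.cwl"}]
        + [{"@id": f"tools/{cid}.cwl"} for cid in sorted(bundle.tools)]
        + [{"@id": f"configs/{iid}.json"} for iid in sorted(bundle.configs)]
        + [{"@id": "job.json"}]
    )

    graph = [
        {
            "@id": "ro-crate-metadata.json",
            "@type": "CreativeWork",
            "conformsTo": [
                {"@id": "https://w3id.org/ro/crate/1.1"},
                {"@id": _PROFILE},
            ],
            "about": {"@id": "./"},
        },
        {
            "@id": "./",
            "@type": "Dataset",
            "name": "provflow exported workflow",
            "description": "Workflow exported from a content-addressed provenance store",
            "mainEntity": {"@id": "workflow.cwl"},
            "hasPart": has_part,
            "author": [{"@id": pid} for pid in sorted(persons)],
            "license": [{"@id": lid} for lid in sorted(licenses)],
        },
        {
            "@id": "workflow.cwl",
            "@type": ["File", "SoftwareSourceCode", "ComputationalWorkflow"],
            "name": "workflow.cwl",
            "programmingLanguage": {"@id": "#cwl"},
            "hasPart": [{"@id": f"#component-{c.id}"} for c in components],
        },
        {
            "@id": "#cwl",
            "@type": "ComputerLanguage",
            "name": "Common Workflow Language",
            "identifier": "https://w3id.org/cwl/v1.2/",
        },
        *component_entities,
        *[persons[k] for k in sorted(persons)],
        *[licenses[k] for k in sorted(licenses)],
    ]
    return {"@context": _CONTEXT, "@graph": graph}


def write_crate(
    registry: Registry, store: Store, tail: str, outdir: str | Path
) -> Path:
    """Write the crate directory: CWL bundle files plus the metadata document."""
    out = Path(outdir)
    bundle = export_cwl(registry, store, tail)
    bundle.write(out)
    manifest = export_rocrate(registry, store, tail, bundle)
    (out / "ro-crate-metadata.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_crate_graph(crate_dir: str | Path) -> dict:
    return json.loads((Path(crate_dir) / "ro-crate-metadata.json").read_text())


def check_crate(manifest: dict, crate_dir: str | Path | None = None) -> list[str]:
    """Structural profile checks for a Workflow RO-Crate metadata document."""
    errors: list[str] = []
    if manifest.get("@context") != _CONTEXT:
        errors.append("wrong or missing @context")
    graph = manifest.get("@graph", [])
    by_id = {e.get("@id"): e for e in graph}
    meta = by_id.get("ro-crate-metadata.json")
    root = by_id.get("./")
    if meta is None:
        errors.append("missing metadata descriptor entity")
    elif meta.get("about", {}).get("@id") != "./":
        errors.append("metadata descriptor does not point at the root dataset")
    if root is None:
        errors.append("missing root dataset entity")
    else:
        if root.get("@type") != "Dataset":
            errors.append("root entity is not a Dataset")
        main = root.get("mainEntity", {}).get("@id")
        if main is None or main not in by_id:
            errors.append("root dataset has no resolvable mainEntity workflow")
        else:
            wf_types = by_id[main].get("@type", [])
            if "ComputationalWorkflow" not in wf_types:
                errors.append("main entity is not typed ComputationalWorkflow")
        for ref in root.get("author", []):
            if ref["@id"] not in by_id:
                errors.append(f"dangling author reference {ref['@id']!r}")
        for ref in root.get("license", []):
            if ref["@id"] not in by_id:
                errors.append(f"dangling license reference {ref['@id']!r}")
    for entity in graph:
        if entity.get("@type") == "SoftwareApplication":
            for ref in entity.get("author", []):
                if ref["@id"] not in by_id:
                    errors.append(f"{entity['@id']}: dangling author {ref['@id']!r}")
            lic = entity.get("license", {}).get("@id")
            if lic is not None and lic not in by_id:
                errors.append(f"{entity['@id']}: dangling license {lic!r}")
    if crate_dir is not None and root is not None:
        for part in root.get("hasPart", []):
            if not (Path(crate_dir) / part["@id"]).exists():
                errors.append(f"hasPart file missing on disk: {part['@id']}")
    return errors
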