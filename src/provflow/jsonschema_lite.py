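"""A small JSON Schema (draft-07 subset) validator.

Used to validate prompt configuration objects against their declared
``config_schema`` and exported BioCompute documents against the bundled
structural schema.  Supports the keywords those schemas actually use:

``type`` (including unions), ``properties``, ``required``,
``additionalProperties``, ``items``, ``enum``, ``const``, ``pattern``,
``minimum`` / ``maximum``, ``minLength`` / ``maxLength``,
``minItems`` / ``maxItems``, ``oneOf`` / ``anyOf`` / ``allOf``, and local
``$ref`` into ``definitions`` / ``$defs``.  ``format`` is accepted and
ignored, as draft-07 permits.
"""

from __future__ import annotations

import re
from typing import Any

__all__ = ["validate", "iter_errors", "SchemaError"]

_TYPE_CHECKS = {
    "object": lambda v: isinstance(v, dict),
    "array": lambda v: isinstance(v, list),
    "string": lambda v: isinstance(v, str),
    "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
    "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
    "boolean": lambda v: isinstance(v, bool),
    "null": lambda v: v is None,
}


class SchemaError(ValueError):
    """The schema itself is malformed or uses an unsupported $ref."""


def _resolve_ref(ref: str, root: dict) -> Any:
    if not ref.startswith("#/"):
        raise SchemaError(f"only local $ref supported, got {ref!r}")
    node: Any = root
    for part in ref[2:].split("/"):
        part = part.replace("~1", "/").replace("~0", "~")
        if not isinstance(node, dict) or part not in node:
            raise SchemaError(f"unresolvable $ref {ref!r}")
        node = node[part]
    return node


def iter_errors(instance: Any, schema: Any, root: dict | None = None, path: str = "$"):
    """Yield human-readable error strings for every violation found."""
    if root is None:
        root = schema if isinstance(schema, dict) else {}
    if schema is True or schema == {}:
        return
    if schema is False:
        yield f"{path}: no value permitted"
        return
    if not isinstance(schema, dict):
        raise SchemaError(f"schema at {path} is not an object")

    if "$ref" in schema:
        yield from iter_errors(instance, _resolve_ref(schema["$ref"], root), root, path)
        return

    if "type" in schema:
        types = schema["type"]
        if isinstance(types, str):
            types = [types]
        if not any(_TYPE_CHECKS[t](instance) for t in types):
            yield f"{path}: expected type {'/'.join(types)}, got {type(instance).__name__}"
            return  # deeper keyword checks would be meaningless

    if "enum" in schema and instance not in schema["enum"]:
        yield f"{path}: {instance!r} not in enum {schema['enum']!r}"
    if "const" in schema and instance != schema["const"]:
        yield f"{path}: {instance!r} != const {schema['const']!r}"

    if isinstance(instance, str):
        if "pattern" in schema and not re.search(schema["pattern"], instance):
            yield f"{path}: {instance!r} does not match pattern {schema['pattern']!r}"
        if "minLength" in schema and len(instance) < schema["minLength"]:
            yield f"{path}: shorter than minLength {schema['minLength']}"
        if "maxLength" in schema and len(instance) > schema["maxLength"]:
            yield f"{path}: longer than maxLength {schema['maxLength']}"

    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        if "minimum" in schema and instance < schema["minimum"]:
            yield f"{path}: {instance} < minimum {schema['minimum']}"
        if "maximum" in schema and instance > schema["maximum"]:
            yield f"{path}: {instance} > maximum {schema['maximum']}"

    if isinstance(instance, list):
        if "minItems" in schema and len(instance) < schema["minItems"]:
            yield f"{path}: fewer than minItems {schema['minItems']}"
        if "maxItems" in schema and len(instance) > schema["maxItems"]:
            yield f"{path}: more than maxItems {schema['maxItems']}"
        if "items" in schema:
            for i, item in enumerate(instance):
                yield from iter_errors(item, schema["items"], root, f"{path}[{i}]")

    if isinstance(instance, dict):
        props = schema.get("properties", {})
        for key in schema.get("required", []):
            if key not in instance:
                yield f"{path}: missing required property {key!r}"
        for key, sub in props.items():
            if key in instance:
                yield from iter_errors(instance[key], sub, root, f"{path}.{key}")
        addl = schema.get("additionalProperties", True)
        if addl is not True:
            for key in instance:
                if key not in props:
                    if addl is False:
                        yield f"{path}: additional property {key!r} not allowed"
                    else:
                        yield from iter_errors(instance[key], addl, root, f"{path}.{key}")

    for comb in ("allOf",):
        for i, sub in enumerate(schema.get(comb, [])):
            yield from iter_errors(instance, sub, root, f"{path}<{comb}[{i}]>")
    if "anyOf" in schema:
        branches = [list(iter_errors(instance, s, root, path)) for s in schema["anyOf"]]
        if all(branches):
            yield f"{path}: no anyOf branch matched"
    if "oneOf" in schema:
        matched = sum(not list(iter_errors(instance, s, root, path)) for s in schema["oneOf"])
        if matched != 1:
            yield f"{path}: {matched} oneOf branches matched, expected exactly 1"


def validate(instance: Any, schema: Any) -> list[str]:
    """Return the list of violations (empty when the instance conforms)."""
    return list(iter_errors(instance, schema))
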