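"""Typed component registry and the type-compatibility graph.

A workflow is assembled from *components*, each a typed building block of
one of three kinds:

* a **prompt** captures a user decision as a JSON configuration object and
  produces a value (a prompt with no inputs injects an initial value);
* a **resolver** is a pure function from one or more typed inputs to a
  single typed output;
* a **view** turns a value into a structured visualization description.

Components declare their inputs and output as *semantic types* — named,
codec-equipped data kinds such as a gene set or a count matrix, rather
than bare strings or files.  Types and components together form a directed
graph (types as nodes, components as edges) that the engine queries to
enumerate which steps can legally follow the values produced so far.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping

import networkx as nx

from .canonical import canonical_json

__all__ = [
    "SemanticType",
    "Component",
    "Registry",
    "RegistryConflictError",
    "RegistryValidationError",
    "tokenize",
]

KINDS = ("prompt", "resolver", "view")
_KIND_ORDER = {k: i for i, k in enumerate(KINDS)}


class RegistryConflictError(ValueError):
    """A different spec was already registered under the same id."""


class RegistryValidationError(ValueError):
    """A spec violates a registry invariant (e.g. dangling type reference)."""


def _identity(value: Any) -> Any:
    return value


@dataclass(frozen=True)
class SemanticType:
    """A named data kind with a codec to/from canonical JSON values.

    The default codec is the identity: values are already JSON-compatible.
    A custom codec must round-trip (``decode(encode(v)) == v``).
    """

    id: str
    label: str
    description: str = ""
    encode: Callable[[Any], Any] = _identity
    decode: Callable[[Any], Any] = _identity

    def signature(self) -> dict:
        return {"id": self.id, "label": self.label, "description": self.description}


@dataclass(frozen=True)
class Component:
    """A workflow building block: prompt, resolver, or view.

    ``run`` receives ``(inputs, config)`` where *inputs* maps declared
    input names to decoded values and *config* is the prompt configuration
    (``None`` for resolvers and views), and returns the output value.

    ``story`` is a parameterized methods-style sentence describing what the
    step does; its ``{placeholders}`` may reference declared input names or
    config property names and are substituted in the generated report.
    ``citations`` maps citation keys (which the report numbers and
    deduplicates) to full reference strings.
    """

    id: str
    kind: str
    label: str
    description: str
    output: str
    inputs: Mapping[str, str] = field(default_factory=dict)
    run: Callable[[Mapping[str, Any], Any], Any] | None = None
    config_schema: dict | None = None
    story: str = ""
    citations: Mapping[str, str] = field(default_factory=dict)
    authors: tuple[str, ...] = ()
    license: str = "CC-BY-4.0"
    version: str = "1.0.0"

    def signature(self) -> dict:
        """Content signature used for idempotence/conflict checks."""
        return {
            "id": self.id,
            "kind": self.kind,
            "label": self.label,
            "description": self.description,
            "inputs": dict(self.inputs),
            "output": self.output,
            "config_schema": self.config_schema,
            "story": self.story,
            "citations": dict(self.citations),
            "authors": list(self.authors),
            "license": self.license,
            "version": self.version,
        }

    def story_placeholders(self) -> set[str]:
        return {
            fname
            for _, fname, _, _ in string.Formatter().parse(self.story)
            if fname
        }


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> set[str]:
    """Case-folded alphanumeric token set used for suggestion scoring."""
    return set(_TOKEN_RE.findall(text.casefold()))


class Registry:
    """Holds semantic types and components; builds the type graph."""

    def __init__(self) -> None:
        self._types: dict[str, SemanticType] = {}
        self._components: dict[str, Component] = {}

    # -- registration -------------------------------------------------

    def register_type(self, spec: SemanticType) -> str:
        existing = self._types.get(spec.id)
        if existing is not None:
            if existing.signature() != spec.signature():
                raise RegistryConflictError(
                    f"semantic type {spec.id!r} already registered with different content"
                )
            return spec.id
        self._types[spec.id] = spec
        return spec.id

    def register_component(self, spec: Component) -> str:
        problems = self._component_problems(spec)
        if problems:
            raise RegistryValidationError("; ".join(problems))
        existing = self._components.get(spec.id)
        if existing is not None:
            if existing.signature() != spec.signature():
                raise RegistryConflictError(
                    f"component {spec.id!r} already registered with different content"
                )
            return spec.id
        self._components[spec.id] = spec
        return spec.id

    def _component_problems(self, spec: Component) -> list[str]:
        problems = []
        if spec.kind not in KINDS:
            problems.append(f"{spec.id}: unknown kind {spec.kind!r}")
        if spec.kind in ("resolver", "view") and not spec.inputs:
            problems.append(f"{spec.id}: {spec.kind} must declare at least one input")
        if spec.kind != "prompt" and spec.config_schema is not None:
            problems.append(f"{spec.id}: only prompts take a config_schema")
        for name, tid in spec.inputs.items():
            if tid not in self._types:
                problems.append(f"{spec.id}: input {name!r} references unknown type {tid!r}")
        if spec.output not in self._types:
            problems.append(f"{spec.id}: output references unknown type {spec.output!r}")
        allowed = set(spec.inputs)
        if spec.config_schema:
            allowed |= set(spec.config_schema.get("properties", {}))
        bad = spec.story_placeholders() - allowed
        if bad:
            problems.append(
                f"{spec.id}: story placeholders {sorted(bad)} are not declared inputs/config"
            )
        return problems

    # -- lookup -------------------------------------------------------

    def get_type(self, type_id: str) -> SemanticType:
        try:
            return self._types[type_id]
        except KeyError:
            raise KeyError(f"unknown semantic type {type_id!r}") from None

    def get_component(self, component_id: str) -> Component:
        try:
            return self._components[component_id]
        except KeyError:
            raise KeyError(f"unknown component {component_id!r}") from None

    @property
    def types(self) -> Mapping[str, SemanticType]:
        return dict(self._types)

    @property
    def components(self) -> Mapping[str, Component]:
        return dict(self._components)

    # -- validation ---------------------------------------------------

    def validate(self) -> list[str]:
        """Return every invariant violation in the registry (empty = well-formed)."""
        report: list[str] = []
        for spec in self._components.values():
            report.extend(self._component_problems(spec))
        return report

    # -- the type graph ----------------------------------------------

    def type_graph(self) -> nx.MultiDiGraph:
        """Directed multigraph: semantic types as nodes, components as edges.

        A component with k inputs contributes k parallel edges (one per
        input type) all pointing at its output type; a zero-input prompt
        contributes an edge from the synthetic start node ``__start__``.
        """
        g = nx.MultiDiGraph()
        for tid in self._types:
            g.add_node(tid)
        for comp in self._components.values():
            if comp.inputs:
                for name, tid in comp.inputs.items():
                    g.add_edge(tid, comp.output, key=f"{comp.id}:{name}", component=comp.id)
            else:
                g.add_edge("__start__", comp.output, key=f"{comp.id}:", component=comp.id)
        return g

    def type_graph_bytes(self) -> bytes:
        """Canonical serialization of the type graph (stable across rebuilds)."""
        g = self.type_graph()
        doc = {
            "nodes": sorted(g.nodes),
            "edges": sorted(
                [u, v, k, d["component"]] for u, v, k, d in g.edges(keys=True, data=True)
            ),
        }
        return canonical_json(doc)

    # -- next-step enumeration ---------------------------------------

    @staticmethod
    def _order_key(comp: Component) -> tuple:
        return (_KIND_ORDER[comp.kind], comp.label, comp.id)

    def next_steps(self, available_types: Iterable[str]) -> list[str]:
        """Component ids applicable given the set of available type ids.

        A component is applicable iff every declared input type is
        available; zero-input prompts are always applicable.  Order is
        deterministic: (prompt < resolver < view, label, id).
        """
        avail = set(available_types)
        unknown = avail - set(self._types)
        if unknown:
            raise KeyError(f"unknown semantic type ids: {sorted(unknown)}")
        hits = [
            c for c in self._components.values()
            if set(c.inputs.values()) <= avail
        ]
        return [c.id for c in sorted(hits, key=self._order_key)]

    def suggest_next(
        self, text: str, available_types: Iterable[str], k: int
    ) -> list[tuple[str, float]]:
        """Rank applicable components by lexical overlap with *text*.

        score = |tokens(text) ∩ tokens(label+description)|
                / (1 + |tokens(label+description)|),
        ties broken by (label, id).  A deterministic baseline; LLM-backed
        choosers can plug in behind the same contract.
        """
        if k <= 0:
            raise ValueError("k must be positive")
        query = tokenize(text)
        scored = []
        for cid in self.next_steps(available_types):
            comp = self._components[cid]
            doc = tokenize(comp.label + " " + comp.description)
            score = len(query & doc) / (1 + len(doc))
            scored.append((comp, score))
        scored.sort(key=lambda cs: (-cs[1], cs[0].label, cs[0].id))
        return [(c.id, s) for c, s in scored[:k]]

    # -- manifest export ----------------------------------------------

    def manifest(self) -> list[dict]:
        """JSON-compatible listing of all components with their metadata."""
        out = []
        for comp in sorted(self._components.values(), key=self._order_key):
            out.append(
                {
                    "id": comp.id,
                    "kind": comp.kind,
                    "label": comp.label,
                    "description": comp.description,
                    "inputs": dict(comp.inputs),
                    "output": comp.output,
                    "story": comp.story,
                    "authors": list(comp.authors),
                    "license": comp.license,
                    "version": comp.version,
                }
            )
        return out
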