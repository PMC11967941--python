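"""Methods-report generation by stacking per-step story sentences.

Each component carries a parameterized, methods-style story sentence.
The report renders one sentence per workflow step in workflow order,
substitutes prompt-configuration values and input type labels into the
placeholders, appends numbered citation markers, and assembles a single
methods paragraph plus a deduplicated bibliography numbered in first-
appearance order.

An optional ``postprocess`` hook (default: identity) lets callers plug
in a copyediting pass — e.g. an LLM rewrite — over the stacked
paragraph; the core never makes model calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from ..registry import Registry
from ..store import Store

__all__ = ["Report", "ReportStep", "build_report"]


@dataclass(frozen=True)
class ReportStep:
    label: str
    story: str  # substituted sentence including citation markers
    output_summary: str
    timestamp: str | None


@dataclass(frozen=True)
class Report:
    steps: tuple[ReportStep, ...]
    methods: str
    bibliography: tuple[tuple[int, str, str], ...]  # (number, key, reference)

    def to_markdown(self, title: str = "Workflow report") -> str:
        lines = [f"# {title}", ""]
        for i, step in enumerate(self.steps, start=1):
            lines.append(f"## Step {i}: {step.label}")
            lines.append("")
            lines.append(step.story)
            if step.output_summary:
                lines.append("")
                lines.append(f"*Output:* {step.output_summary}")
            if step.timestamp:
                lines.append(f"*Executed:* {step.timestamp}")
            lines.append("")
        lines.append("## Methods")
        lines.append("")
        lines.append(self.methods if self.methods else "(empty workflow)")
        lines.append("")
        if self.bibliography:
            lines.append("## References")
            lines.append("")
            for number, _key, text in self.bibliography:
                lines.append(f"{number}. {text}")
            lines.append("")
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "steps": [
                {
                    "label": s.label,
                    "story": s.story,
                    "output_summary": s.output_summary,
                    "timestamp": s.timestamp,
                }
                for s in self.steps
            ],
            "methods": self.methods,
            "bibliography": [
                {"number": n, "key": k, "reference": t} for n, k, t in self.bibliography
            ],
        }


def _summarize_value(type_id: str, value) -> str:
    if isinstance(value, dict):
        if "genes" in value:
            return f"a gene set of {len(value['genes'])} genes"
        if "entries" in value:
            return f"a library of {len(value['entries'])} gene sets"
        if value.get("kind"):
            return f"a {value['kind']} visualization"
        if "counts" in value and "samples" in value:
            return f"a {len(value.get('genes', []))}×{len(value['samples'])} count matrix"
    if isinstance(value, list):
        return f"a list of {len(value)} items"
    return f"a {type_id} value"


def build_report(
    registry: Registry,
    store: Store,
    tail: str | None,
    postprocess: Callable[[str], str] | None = None,
) -> Report:
    """Assemble the report for the workflow ending at *tail*.

    Steps without stored results get placeholder summaries.  Citation
    keys are numbered in first-appearance order and deduplicated across
    steps; every marker in a story refers to the shared bibliography.
    """
    chain = store.resolve_list(tail)
    numbers: dict[str, int] = {}
    bibliography: list[tuple[int, str, str]] = []
    steps: list[ReportStep] = []

    for pid in chain:
        rec = store.get_process(pid)
        comp = registry.get_component(rec.component_id)

        params: dict[str, str] = {}
        if isinstance(rec.config, dict):
            params.update({k: str(v) for k, v in rec.config.items()})
        for name, input_pid in rec.inputs.items():
            input_comp = registry.get_component(store.get_process(input_pid).component_id)
            params.setdefault(name, registry.get_type(input_comp.output).label.lower())
        try:
            sentence = comp.story.format(**params) if comp.story else comp.label + "."
        except KeyError:
            sentence = comp.story  # unresolvable placeholder left verbatim

        marks = []
        for key in comp.citations:
            if key not in numbers:
                numbers[key] = len(numbers) + 1
                bibliography.append((numbers[key], key, comp.citations[key]))
            marks.append(numbers[key])
        if marks:
            sentence += " [" + ",".join(str(m) for m in sorted(marks)) + "]"

        result = store.get_result(pid)
        if result is None:
            summary, timestamp = "(not yet executed)", None
        elif result.status == "ok":
            blob = store.get_data(result.data_id)
            summary, timestamp = _summarize_value(blob.semantic_type_id, blob.value), result.timestamp
        else:
            summary, timestamp = f"failed: {result.error}", result.timestamp
        steps.append(ReportStep(comp.label, sentence, summary, timestamp))

    methods = " ".join(s.story for s in steps)
    if postprocess is not None:
        methods = postprocess(methods)
    return Report(tuple(steps), methods, tuple(bibliography))
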