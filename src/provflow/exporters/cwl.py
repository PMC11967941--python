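"""CWL v1.2 export of stored workflows, plus a minimal bundle runner.

Every component becomes a ``CommandLineTool`` wrapping the engine's own
``provflow invoke`` command-line interface: inputs arrive as JSON files,
the output is written to a JSON file, and prompt configurations are
workflow-level inputs bound in the job document.  License, authorship,
and versioning metadata for each component ride along as schema.org
fields.

Because execution happens through the CLI with canonical-JSON files, a
generic CWL runner reproduces the engine's stored result payloads
byte-for-byte.  :func:`run_cwl_bundle` is a deliberately small runner —
it topologically executes the exported tools via subprocess exactly as
their command lines specify — used to exercise that round trip.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..canonical import canonical_json
from ..registry import Registry
from ..store import Store

__all__ = ["CWLBundle", "export_cwl", "validate_cwl_bundle", "run_cwl_bundle"]

DEFAULT_BASE_COMMAND = ("provflow", "invoke")


@dataclass
class CWLBundle:
    """An exported workflow: CWL Workflow + per-component tools + job inputs."""

    workflow: dict
    tools: dict[str, dict]  # component id -> CommandLineTool document
    job: dict  # job-input document (File bindings for prompt configs)
    configs: dict[str, dict]  # workflow-input id -> prompt config object
    step_processes: dict[str, str] = field(default_factory=dict)  # step id -> process id

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir)
        (out / "tools").mkdir(parents=True, exist_ok=True)
        (out / "configs").mkdir(exist_ok=True)
        (out / "workflow.cwl").write_text(yaml.safe_dump(self.workflow, sort_keys=False))
        for cid, tool in self.tools.items():
            (out / "tools" / f"{cid}.cwl").write_text(yaml.safe_dump(tool, sort_keys=False))
        for input_id, config in self.configs.items():
            (out / "configs" / f"{input_id}.json").write_bytes(canonical_json(config))
        (out / "job.json").write_text(json.dumps(self.job, indent=2, sort_keys=True))
        return out


def _tool_document(comp, base_command: tuple[str, ...]) -> dict:
    inputs: dict = {}
    if comp.kind == "prompt":
        inputs["config"] = {
            "type": "File",
            "inputBinding": {"prefix": "--config", "position": 1},
        }
    for pos, name in enumerate(sorted(comp.inputs), start=2):
        inputs[name] = {
            "type": "File",
            "inputBinding": {"prefix": f"{name}=", "separate": False, "position": pos},
        }
    return {
        "cwlVersion": "v1.2",
        "class": "CommandLineTool",
        "id": comp.id,
        "label": comp.label,
        "doc": comp.description,
        "baseCommand": list(base_command) + [comp.id],
        "arguments": ["--output", "output.json"],
        "inputs": inputs,
        "outputs": {
            "output": {"type": "File", "outputBinding": {"glob": "output.json"}}
        },
        "$namespaces": {"s": "https://schema.org/"},
        "s:license": comp.license,
        "s:author": [{"class": "s:Person", "s:name": a} for a in comp.authors],
        "s:softwareVersion": comp.version,
    }


def export_cwl(
    registry: Registry,
    store: Store,
    tail: str,
    base_command: tuple[str, ...] = DEFAULT_BASE_COMMAND,
) -> CWLBundle:
    """Export the workflow ending at *tail* as a CWL v1.2 bundle.

    Step ids follow workflow order (``step0`` …); prompt configurations
    become workflow-level File inputs referenced from the job document.
    """
    chain = store.resolve_list(tail)
    if not chain:
        raise ValueError("cannot export an empty workflow")
    closure = store.process_closure(list(chain))
    outside = set(closure) - set(chain)
    if outside:
        raise ValueError(f"workflow references processes outside its step list: {sorted(outside)}")

    step_ids = {pid: f"step{i}" for i, pid in enumerate(chain)}
    tools: dict[str, dict] = {}
    wf_inputs: dict[str, dict] = {}
    steps: dict[str, dict] = {}
    job: dict[str, dict] = {}
    configs: dict[str, dict] = {}

    for pid in chain:
        rec = store.get_process(pid)
        comp = registry.get_component(rec.component_id)
        if comp.id not in tools:
            tools[comp.id] = _tool_document(comp, base_command)
        sid = step_ids[pid]
        bindings: dict[str, str] = {}
        if comp.kind == "prompt":
            input_id = f"{sid}_config"
            wf_inputs[input_id] = {"type": "File", "doc": f"configuration for {comp.label}"}
            bindings["config"] = input_id
            job[input_id] = {"class": "File", "path": f"configs/{input_id}.json"}
            configs[input_id] = rec.config if rec.config is not None else {}
        for name, dep in rec.inputs.items():
            bindings[name] = f"{step_ids[dep]}/output"
        steps[sid] = {
            "run": f"tools/{comp.id}.cwl",
            "in": bindings,
            "out": ["output"],
        }

    workflow = {
        "cwlVersion": "v1.2",
        "class": "Workflow",
        "id": "main",
        "label": "provflow exported workflow",
        "inputs": wf_inputs,
        "steps": steps,
        "outputs": {
            "final_output": {
                "type": "File",
                "outputSource": f"{step_ids[chain[-1]]}/output",
            }
        },
    }
    return CWLBundle(workflow, tools, job, configs, {v: k for k, v in step_ids.items()})


def validate_cwl_bundle(
    bundle: CWLBundle, registry: Registry | None = None, store: Store | None = None
) -> list[str]:
    """Structural validation of an exported bundle.

    Checks document classes and versions, step wiring (every source
    resolves to a workflow input or an upstream step output), tool
    input/metadata completeness, and — when the store is given — that the
    step graph is isomorphic to the process dependency graph.
    """
    errors: list[str] = []
    wf = bundle.workflow
    if wf.get("cwlVersion") != "v1.2":
        errors.append("workflow: cwlVersion must be v1.2")
    if wf.get("class") != "Workflow":
        errors.append("workflow: class must be Workflow")
    steps = wf.get("steps", {})
    for sid, step in steps.items():
        run = step.get("run", "")
        cid = Path(run).stem
        if cid not in bundle.tools:
            errors.append(f"{sid}: run references missing tool {run!r}")
        for name, source in step.get("in", {}).items():
            if "/" in source:
                src_step, src_port = source.split("/", 1)
                if src_step not in steps:
                    errors.append(f"{sid}.{name}: unknown source step {src_step!r}")
                elif src_port not in steps[src_step].get("out", []):
                    errors.append(f"{sid}.{name}: source port {source!r} not produced")
            elif source not in wf.get("inputs", {}):
                errors.append(f"{sid}.{name}: unknown workflow input {source!r}")
    for out_id, out in wf.get("outputs", {}).items():
        src = out.get("outputSource", "")
        if src.split("/", 1)[0] not in steps:
            errors.append(f"output {out_id}: bad outputSource {src!r}")
    for cid, tool in bundle.tools.items():
        if tool.get("class") != "CommandLineTool":
            errors.append(f"tool {cid}: class must be CommandLineTool")
        if tool.get("cwlVersion") != "v1.2":
            errors.append(f"tool {cid}: cwlVersion must be v1.2")
        if not tool.get("baseCommand"):
            errors.append(f"tool {cid}: missing baseCommand")
        for meta in ("s:license", "s:author", "s:softwareVersion"):
            if not tool.get(meta):
                errors.append(f"tool {cid}: missing {meta}")
        if registry is not None:
            comp = registry.get_component(cid)
            expected = set(comp.inputs) | ({"config"} if comp.kind == "prompt" else set())
            if set(tool.get("inputs", {})) != expected:
                errors.append(f"tool {cid}: inputs do not match component declaration")
    if store is not None and bundle.step_processes:
        step_edges = {
            (source.split("/", 1)[0], sid)
            for sid, step in steps.items()
            for source in step.get("in", {}).values()
            if "/" in source
        }
        proc_of = bundle.step_processes
        process_edges = {
            (sid_of_dep, sid)
            for sid, pid in proc_of.items()
            for dep in store.get_process(pid).inputs.values()
            for sid_of_dep in [next(s for s, p in proc_of.items() if p == dep)]
        }
        if step_edges != process_edges:
            errors.append("step graph is not isomorphic to the process dependency graph")
    return errors


def _topo_order(steps: dict[str, dict]) -> list[str]:
    deps = {
        sid: {s.split("/", 1)[0] for s in step.get("in", {}).values() if "/" in s}
        for sid, step in steps.items()
    }
    order, done = [], set()
    while len(order) < len(steps):
        progress = False
        for sid in sorted(steps):
            if sid not in done and deps[sid] <= done:
                order.append(sid)
                done.add(sid)
                progress = True
        if not progress:
            raise ValueError("cycle in workflow steps")
    return order


def run_cwl_bundle(bundle_dir: str | Path, job_path: str | Path | None = None) -> dict[str, bytes]:
    """Execute a written CWL bundle step by step via subprocess.

    A minimal runner: reads the workflow and tool documents, resolves
    File sources from the job document and upstream outputs, invokes each
    tool's command line in a scratch directory, and returns the output
    bytes per step id.
    """
    bundle_dir = Path(bundle_dir)
    wf = yaml.safe_load((bundle_dir / "workflow.cwl").read_text())
    job = json.loads(Path(job_path or bundle_dir / "job.json").read_text())
    steps = wf["steps"]
    outputs: dict[str, Path] = {}
    results: dict[str, bytes] = {}

    with tempfile.TemporaryDirectory() as scratch:
        for sid in _topo_order(steps):
            step = steps[sid]
            tool = yaml.safe_load((bundle_dir / step["run"]).read_text())
            argv = list(tool["baseCommand"]) + [str(a) for a in tool.get("arguments", [])]
            bound = []
            for name, source in step.get("in", {}).items():
                if "/" in source:
                    path = outputs[source.split("/", 1)[0]]
                else:
                    path = bundle_dir / job[source]["path"]
                binding = tool["inputs"][name]["inputBinding"]
                prefix = binding.get("prefix", "")
                if binding.get("separate", True):
                    bound.append((binding.get("position", 0), [prefix, str(path)]))
                else:
                    bound.append((binding.get("position", 0), [f"{prefix}{path}"]))
            for _, part in sorted(bound, key=lambda b: b[0]):
                argv.extend(part)
            workdir = Path(scratch) / sid
            workdir.mkdir()
            proc = subprocess.run(argv, cwd=workdir, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(f"{sid} failed ({argv}): {proc.stderr}")
            glob = tool["outputs"]["output"]["outputBinding"]["glob"]
            out_file = workdir / glob
            outputs[sid] = out_file
            results[sid] = out_file.read_bytes()
    return results
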