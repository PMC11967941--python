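"""Memoized, dependency-aware execution of stored workflows.

Requests for the output of any process go through a ready-queue of
in-process workers.  A process is executed at most once per store
lifetime: if a result record already exists it is returned without
invoking the component.  A component's ``run`` contract must be a pure
function of its decoded inputs and configuration — that purity is what
makes memoization by content address sound.  Components wrapping external
services must set ``external=True`` on their results so downstream
consumers can see the reproducibility caveat (the bundled fixture library
contains none).

Failed runs are stored as error results and are memoized like successes;
a dependent of a failed process receives a dependency-failure error
without its own ``run`` ever being invoked.  Failures are never retried
automatically; ``force=True`` drops the memoized record and re-executes.
"""

from __future__ import annotations

import json
import threading
from collections import Counter
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, TextIO

from .registry import Registry
from .store import ResultRecord, Store

__all__ = ["ExecutionLog", "Executor"]


def _utcnow() -> str:
    return datetime.now(timezone.utc).isoformat()


@dataclass
class ExecutionLog:
    """Ordered event list plus a per-process execution counter.

    Events are dicts with an ``event`` field (enqueue | start | finish |
    memoized) and a ``process`` field; they can be streamed as JSON lines.
    """

    events: list[dict] = field(default_factory=list)
    executions: Counter = field(default_factory=Counter)
    _lock: threading.Lock = field(default_factory=threading.Lock, repr=False)
    stream: TextIO | None = None

    def emit(self, event: str, process_id: str, **extra: Any) -> None:
        rec = {"event": event, "process": process_id, **extra}
        with self._lock:
            self.events.append(rec)
            if event == "start":
                self.executions[process_id] += 1
            if self.stream is not None:
                self.stream.write(json.dumps(rec, sort_keys=True) + "\n")

    def count(self, process_id: str) -> int:
        return self.executions[process_id]


class Executor:
    """Resolves results on demand with memoization and a worker pool."""

    def __init__(
        self,
        registry: Registry,
        store: Store,
        workers: int = 4,
        log: ExecutionLog | None = None,
    ) -> None:
        if workers < 1:
            raise ValueError("workers must be positive")
        self.registry = registry
        self.store = store
        self.workers = workers
        self.log = log if log is not None else ExecutionLog()
        self._store_lock = threading.Lock()
        self._inflight: dict[str, threading.Event] = {}
        self._inflight_lock = threading.Lock()

    # -- single-process resolution ------------------------------------

    def request_result(self, process_id: str, force: bool = False) -> ResultRecord:
        """Return the result for *process_id*, executing it if necessary.

        Inputs are resolved recursively first.  With ``force=True`` the
        memoized record for this process (only) is discarded and recomputed.
        """
        if force:
            with self._store_lock:
                self.store.delete_result(process_id)
        return self._resolve(process_id)

    def _resolve(self, process_id: str) -> ResultRecord:
        # Memoization check and in-flight guard: at most one execution per
        # process id even under concurrent requests.
        while True:
            with self._store_lock:
                existing = self.store.get_result(process_id)
            if existing is not None:
                self.log.emit("memoized", process_id)
                return existing
            with self._inflight_lock:
                ev = self._inflight.get(process_id)
                if ev is None:
                    self._inflight[process_id] = threading.Event()
                    break
            ev.wait()

        try:
            result = self._execute(process_id)
        finally:
            with self._inflight_lock:
                self._inflight.pop(process_id).set()
        return result

    def _execute(self, process_id: str) -> ResultRecord:
        with self._store_lock:
            rec = self.store.get_process(process_id)
        comp = self.registry.get_component(rec.component_id)

        input_results = {name: self._resolve(pid) for name, pid in rec.inputs.items()}
        failed = {name: r for name, r in input_results.items() if r.status != "ok"}
        if failed:
            result = ResultRecord(
                process_id=process_id,
                status="error",
                data_id=None,
                error={
                    "type": "dependency-failure",
                    "failed_inputs": {n: r.process_id for n, r in failed.items()},
                },
                timestamp=_utcnow(),
            )
            with self._store_lock:
                self.store.put_result(result)
            self.log.emit("dep_failed", process_id)
            return result

        decoded = {}
        for name, r in input_results.items():
            with self._store_lock:
                blob = self.store.get_data(r.data_id)
            stype = self.registry.get_type(blob.semantic_type_id)
            decoded[name] = stype.decode(blob.value)

        self.log.emit("start", process_id)
        out_type = self.registry.get_type(comp.output)
        try:
            if comp.run is None:
                raise RuntimeError(f"component {comp.id!r} has no run contract")
            value = comp.run(decoded, rec.config)
            encoded = out_type.encode(value)
            with self._store_lock:
                data_id = self.store.upsert_data(comp.output, encoded)
                result = ResultRecord(
                    process_id=process_id,
                    status="ok",
                    data_id=data_id,
                    error=None,
                    timestamp=_utcnow(),
                )
                self.store.put_result(result)
        except Exception as exc:  # stored and memoized like a success
            result = ResultRecord(
                process_id=process_id,
                status="error",
                data_id=None,
                error={"type": type(exc).__name__, "message": str(exc)},
                timestamp=_utcnow(),
            )
            with self._store_lock:
                self.store.put_result(result)
        self.log.emit("finish", process_id, status=result.status)
        return result

    # -- whole-workflow execution -------------------------------------

    def run_workflow(self, tail: str | None, parallelism: int | None = None) -> dict[str, ResultRecord]:
        """Resolve every process in the workflow at *tail* (and its inputs).

        Independent ready tasks run concurrently on up to *parallelism*
        workers (default: the executor's pool size); the resulting map of
        process id to result is identical for any level of parallelism.
        """
        workers = self.workers if parallelism is None else parallelism
        if workers < 1:
            raise ValueError("parallelism must be positive")
        chain = self.store.resolve_list(tail)
        if not chain:
            return {}
        closure = self.store.process_closure(list(chain))

        # Kahn-style scheduling: a task is enqueued (FIFO) once all its
        # inputs have finished; ready tasks are dispatched to the pool.
        dependents: dict[str, list[str]] = {pid: [] for pid in closure}
        missing: dict[str, set[str]] = {}
        for pid, rec in closure.items():
            missing[pid] = set(rec.inputs.values())
            for dep in rec.inputs.values():
                dependents[dep].append(pid)

        results: dict[str, ResultRecord] = {}
        done_lock = threading.Lock()
        ready = [pid for pid, deps in sorted(missing.items()) if not deps]
        for pid in ready:
            self.log.emit("enqueue", pid)

        with ThreadPoolExecutor(max_workers=workers) as pool:
            pending = {}

            def submit(pid: str) -> None:
                pending[pid] = pool.submit(self._resolve, pid)

            for pid in ready:
                submit(pid)
            while pending:
                # wait for any task to finish, then release its dependents
                finished = None
                for pid, fut in list(pending.items()):
                    if fut.done():
                        finished = pid
                        break
                if finished is None:
                    next(iter(pending.values())).result()  # block on one
                    continue
                fut = pending.pop(finished)
                results[finished] = fut.result()
                with done_lock:
                    for child in dependents[finished]:
                        missing[child].discard(finished)
                        if not missing[child] and child not in results and child not in pending:
                            self.log.emit("enqueue", child)
                            submit(child)
        return results
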