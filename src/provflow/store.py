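"""The fully persistent, content-addressed provenance store.

Executed workflows live in four tables:

* **process** — the dependency graph: each record holds a component id, an
  optional prompt configuration, and back-references (by name) to the
  processes whose outputs it consumes;
* **fpl** — fully persistent list nodes giving the sequential order of a
  workflow; a workflow is resolved from the id of its last node, and
  shared prefixes are physically shared between workflows;
* **result** — at most one per process: status, output data reference (or
  error payload), and an execution timestamp;
* **data** — canonical-JSON blobs, plus a file table addressing raw bytes
  by SHA-256 and serving them under ``drs://local/<sha256>`` URIs.

Every id is the SHA-256 of the record's canonical serialization with a
record-type tag prefix, so identical content dedupes to one physical row
regardless of insertion order, and editing an interior step is a git-style
rebase that regenerates only the step and its transitive dependents.

Timestamps are metadata on result records and never enter a content hash.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass
from typing import Any, Iterator, Mapping

from . import jsonschema_lite
from .canonical import canonical_json, content_hash
from .registry import Registry

__all__ = [
    "ProcessRecord",
    "FPLNode",
    "ResultRecord",
    "DataBlob",
    "FileEntry",
    "MemoryStore",
    "SqliteStore",
    "Store",
    "NotFoundError",
    "IntegrityError",
    "save_document",
    "load_document",
]

DRS_PREFIX = "drs://local/"


class NotFoundError(KeyError):
    """The referenced id/uri does not exist in the store."""


class IntegrityError(ValueError):
    """A referential-integrity or validation precondition failed."""


@dataclass(frozen=True)
class ProcessRecord:
    id: str
    component_id: str
    config: Any  # JSON object for prompts, None otherwise
    inputs: Mapping[str, str]  # input name -> ProcessRecord id

    @staticmethod
    def compute_id(component_id: str, config: Any, inputs: Mapping[str, str]) -> str:
        return content_hash(
            "process",
            {"component": component_id, "config": config, "inputs": dict(sorted(inputs.items()))},
        )


@dataclass(frozen=True)
class FPLNode:
    id: str
    process_id: str
    parent: str | None

    @staticmethod
    def compute_id(process_id: str, parent: str | None) -> str:
        return content_hash("fpl", {"process": process_id, "parent": parent})


@dataclass(frozen=True)
class ResultRecord:
    process_id: str
    status: str  # "ok" | "error"
    data_id: str | None  # DataBlob id when ok
    error: Any  # error payload when status == "error"
    timestamp: str  # UTC ISO-8601; excluded from all content hashes
    external: bool = False


@dataclass(frozen=True)
class DataBlob:
    id: str
    semantic_type_id: str
    value: Any  # canonical-JSON-compatible value

    @staticmethod
    def compute_id(semantic_type_id: str, value: Any) -> str:
        return content_hash("data", {"type": semantic_type_id, "value": value})


@dataclass(frozen=True)
class FileEntry:
    sha256: str
    size: int
    uri: str
    media_type: str


class Store:
    """Backend-independent store logic; subclasses provide raw table access.

    A registry may be attached to validate component references and prompt
    configurations at ``upsert_process`` time.
    """

    def __init__(self, registry: Registry | None = None) -> None:
        self.registry = registry

    # -- raw table primitives implemented by backends -----------------

    def _put(self, table: str, key: str, row: dict) -> None:
        raise NotImplementedError

    def _get(self, table: str, key: str) -> dict | None:
        raise NotImplementedError

    def _count(self, table: str) -> int:
        raise NotImplementedError

    def _keys(self, table: str) -> Iterator[str]:
        raise NotImplementedError

    # -- processes ----------------------------------------------------

    def upsert_process(
        self, component_id: str, config: Any, inputs: Mapping[str, str] | None = None
    ) -> str:
        inputs = dict(inputs or {})
        if self.registry is not None:
            try:
                comp = self.registry.get_component(component_id)
            except KeyError as exc:
                raise IntegrityError(str(exc)) from exc
            if comp.kind == "prompt":
                if comp.config_schema is not None:
                    errs = jsonschema_lite.validate(config, comp.config_schema)
                    if errs:
                        raise IntegrityError(
                            f"config for {component_id!r} violates its schema: {errs}"
                        )
            elif config is not None:
                raise IntegrityError(f"{component_id!r} is not a prompt; config must be null")
            if set(inputs) != set(comp.inputs):
                raise IntegrityError(
                    f"{component_id!r} expects inputs {sorted(comp.inputs)}, got {sorted(inputs)}"
                )
        for name, pid in inputs.items():
            if self._get("process", pid) is None:
                raise IntegrityError(f"input {name!r} references unknown process {pid!r}")
        pid = ProcessRecord.compute_id(component_id, config, inputs)
        self._put(
            "process",
            pid,
            {"component": component_id, "config": config, "inputs": inputs},
        )
        return pid

    def get_process(self, process_id: str) -> ProcessRecord:
        row = self._get("process", process_id)
        if row is None:
            raise NotFoundError(f"unknown process {process_id!r}")
        return ProcessRecord(process_id, row["component"], row["config"], row["inputs"])

    def process_closure(self, process_ids: Iterator[str] | list[str]) -> dict[str, ProcessRecord]:
        """All processes reachable from *process_ids* via input references."""
        out: dict[str, ProcessRecord] = {}
        stack = list(process_ids)
        while stack:
            pid = stack.pop()
            if pid in out:
                continue
            rec = self.get_process(pid)
            out[pid] = rec
            stack.extend(rec.inputs.values())
        return out

    # -- fully persistent lists ---------------------------------------

    def extend_list(self, tail: str | None, process_id: str) -> str:
        if tail is not None and self._get("fpl", tail) is None:
            raise NotFoundError(f"unknown list node {tail!r}")
        if self._get("process", process_id) is None:
            raise NotFoundError(f"unknown process {process_id!r}")
        nid = FPLNode.compute_id(process_id, tail)
        self._put("fpl", nid, {"process": process_id, "parent": tail})
        return nid

    def resolve_list(self, tail: str | None) -> list[str]:
        """Process ids of the workflow ending at *tail*, head first."""
        chain: list[str] = []
        node = tail
        while node is not None:
            row = self._get("fpl", node)
            if row is None:
                raise NotFoundError(f"unknown list node {node!r}")
            chain.append(row["process"])
            node = row["parent"]
        chain.reverse()
        return chain

    # -- rebase --------------------------------------------------------

    def rebase(
        self,
        tail: str,
        target: str,
        replacement: tuple[str, Any],
    ) -> tuple[str, dict[str, str]]:
        """Replace *target* in the workflow at *tail* with a new (component,
        config) pair, regenerating only the target and its transitive
        dependents; everything else keeps its id (and its results).

        Returns the new tail and the map of changed process ids.
        """
        chain = self.resolve_list(tail)
        if target not in chain:
            raise IntegrityError(f"process {target!r} does not occur in the workflow")
        closure = self.process_closure(list(chain))

        depends: dict[str, bool] = {}

        def depends_on_target(pid: str) -> bool:
            if pid == target:
                return True
            if pid in depends:
                return depends[pid]
            rec = closure.get(pid) or self.get_process(pid)
            depends[pid] = any(depends_on_target(i) for i in rec.inputs.values())
            return depends[pid]

        new_component, new_config = replacement
        mapping: dict[str, str] = {}

        def rewrite(pid: str) -> str:
            if pid in mapping:
                return mapping[pid]
            if not depends_on_target(pid):
                mapping[pid] = pid
                return pid
            rec = closure.get(pid) or self.get_process(pid)
            new_inputs = {name: rewrite(i) for name, i in rec.inputs.items()}
            if pid == target:
                nid = self.upsert_process(new_component, new_config, new_inputs)
            else:
                nid = self.upsert_process(rec.component_id, rec.config, new_inputs)
            mapping[pid] = nid
            return nid

        new_tail: str | None = None
        for pid in chain:
            new_tail = self.extend_list(new_tail, rewrite(pid))
        changed = {old: new for old, new in mapping.items() if old != new}
        assert new_tail is not None
        return new_tail, changed

    # -- results -------------------------------------------------------

    def put_result(self, result: ResultRecord) -> None:
        if self._get("process", result.process_id) is None:
            raise NotFoundError(f"unknown process {result.process_id!r}")
        self._put(
            "result",
            result.process_id,
            {
                "status": result.status,
                "data_id": result.data_id,
                "error": result.error,
                "timestamp": result.timestamp,
                "external": result.external,
            },
        )

    def get_result(self, process_id: str) -> ResultRecord | None:
        row = self._get("result", process_id)
        if row is None:
            return None
        return ResultRecord(
            process_id,
            row["status"],
            row["data_id"],
            row["error"],
            row["timestamp"],
            bool(row["external"]),
        )

    def delete_result(self, process_id: str) -> None:
        """Drop a memoized result so the process can be re-executed (force)."""
        self._delete("result", process_id)

    def _delete(self, table: str, key: str) -> None:
        raise NotImplementedError

    # -- data blobs ----------------------------------------------------

    def upsert_data(self, semantic_type_id: str, value: Any) -> str:
        did = DataBlob.compute_id(semantic_type_id, value)
        self._put("data", did, {"type": semantic_type_id, "value": value})
        return did

    def get_data(self, data_id: str) -> DataBlob:
        row = self._get("data", data_id)
        if row is None:
            raise NotFoundError(f"unknown data blob {data_id!r}")
        return DataBlob(data_id, row["type"], row["value"])

    # -- files ---------------------------------------------------------

    def store_file(self, data: bytes, media_type: str = "application/octet-stream") -> FileEntry:
        sha = hashlib.sha256(data).hexdigest()
        self._put_file(sha, data, media_type)
        return FileEntry(sha, len(data), DRS_PREFIX + sha, media_type)

    def resolve_uri(self, uri: str) -> bytes:
        if not uri.startswith(DRS_PREFIX):
            raise NotFoundError(f"not a resolvable DRS URI: {uri!r}")
        sha = uri[len(DRS_PREFIX):]
        data = self._get_file(sha)
        if data is None:
            raise NotFoundError(f"no stored file for {uri!r}")
        return data

    def _put_file(self, sha: str, data: bytes, media_type: str) -> None:
        raise NotImplementedError

    def _get_file(self, sha: str) -> bytes | None:
        raise NotImplementedError

    # -- bookkeeping ---------------------------------------------------

    def counts(self) -> dict[str, int]:
        return {t: self._count(t) for t in ("process", "fpl", "result", "data", "file")}


class MemoryStore(Store):
    """Pure in-memory backend (dict-of-dicts)."""

    def __init__(self, registry: Registry | None = None) -> None:
        super().__init__(registry)
        self._tables: dict[str, dict[str, dict]] = {
            t: {} for t in ("process", "fpl", "result", "data")
        }
        self._files: dict[str, tuple[bytes, str]] = {}

    def _put(self, table: str, key: str, row: dict) -> None:
        self._tables[table].setdefault(key, row)

    def _get(self, table: str, key: str) -> dict | None:
        return self._tables[table].get(key)

    def _delete(self, table: str, key: str) -> None:
        self._tables[table].pop(key, None)

    def _count(self, table: str) -> int:
        if table == "file":
            return len(self._files)
        return len(self._tables[table])

    def _keys(self, table: str) -> Iterator[str]:
        if table == "file":
            return iter(self._files)
        return iter(self._tables[table])

    def _put_file(self, sha: str, data: bytes, media_type: str) -> None:
        self._files.setdefault(sha, (data, media_type))

    def _get_file(self, sha: str) -> bytes | None:
        entry = self._files.get(sha)
        return entry[0] if entry else None


class SqliteStore(Store):
    """Single-file (or ``:memory:``) relational backend."""

    _SCHEMA = """
    CREATE TABLE IF NOT EXISTS process (id TEXT PRIMARY KEY, row TEXT NOT NULL);
    CREATE TABLE IF NOT EXISTS fpl     (id TEXT PRIMARY KEY, row TEXT NOT NULL);
    CREATE TABLE IF NOT EXISTS result  (id TEXT PRIMARY KEY, row TEXT NOT NULL);
    CREATE TABLE IF NOT EXISTS data    (id TEXT PRIMARY KEY, row TEXT NOT NULL);
    CREATE TABLE IF NOT EXISTS file    (sha256 TEXT PRIMARY KEY,
                                        media_type TEXT NOT NULL,
                                        content BLOB NOT NULL);
    """

    def __init__(self, path: str = ":memory:", registry: Registry | None = None) -> None:
        super().__init__(registry)
        self._conn = sqlite3.connect(path, check_same_thread=False)
        self._conn.executescript(self._SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def _put(self, table: str, key: str, row: dict) -> None:
        self._conn.execute(
            f"INSERT OR IGNORE INTO {table} (id, row) VALUES (?, ?)",
            (key, canonical_json(row).decode("utf-8")),
        )
        self._conn.commit()

    def _get(self, table: str, key: str) -> dict | None:
        cur = self._conn.execute(f"SELECT row FROM {table} WHERE id = ?", (key,))
        hit = cur.fetchone()
        return json.loads(hit[0]) if hit else None

    def _delete(self, table: str, key: str) -> None:
        self._conn.execute(f"DELETE FROM {table} WHERE id = ?", (key,))
        self._conn.commit()

    def _count(self, table: str) -> int:
        cur = self._conn.execute(f"SELECT COUNT(*) FROM {table}")
        return cur.fetchone()[0]

    def _keys(self, table: str) -> Iterator[str]:
        col = "sha256" if table == "file" else "id"
        cur = self._conn.execute(f"SELECT {col} FROM {table}")
        return (r[0] for r in cur.fetchall())

    def _put_file(self, sha: str, data: bytes, media_type: str) -> None:
        self._conn.execute(
            "INSERT OR IGNORE INTO file (sha256, media_type, content) VALUES (?, ?, ?)",
            (sha, media_type, data),
        )
        self._conn.commit()

    def _get_file(self, sha: str) -> bytes | None:
        cur = self._conn.execute("SELECT content FROM file WHERE sha256 = ?", (sha,))
        hit = cur.fetchone()
        return bytes(hit[0]) if hit else None


DOCUMENT_FORMAT = "provflow-workflow/1"


def save_document(store: Store, tail: str | None, include_results: bool = True) -> dict:
    """Serialize the workflow at *tail* into a self-contained JSON document.

    The document embeds every reachable process (with prompt configs), the
    step order, and optionally the results with their timestamps, so that
    loading it into an empty store reconstructs identical ids.
    """
    chain = store.resolve_list(tail)
    closure = store.process_closure(list(chain))
    doc: dict[str, Any] = {
        "format": DOCUMENT_FORMAT,
        "tail": tail,
        "steps": chain,
        "processes": {
            pid: {"component": rec.component_id, "config": rec.config, "inputs": dict(rec.inputs)}
            for pid, rec in sorted(closure.items())
        },
    }
    if include_results:
        results = {}
        for pid in closure:
            res = store.get_result(pid)
            if res is None:
                continue
            entry: dict[str, Any] = {
                "status": res.status,
                "timestamp": res.timestamp,
                "external": res.external,
            }
            if res.status == "ok" and res.data_id is not None:
                blob = store.get_data(res.data_id)
                entry["data"] = {"type": blob.semantic_type_id, "value": blob.value}
            else:
                entry["error"] = res.error
            results[pid] = entry
        doc["results"] = results
    return doc


def load_document(store: Store, doc: dict) -> str | None:
    """Load a workflow document into *store*; returns the reconstructed tail.

    Raises :class:`IntegrityError` if recomputed ids disagree with the
    document (tampered or incompatible content).
    """
    if doc.get("format") != DOCUMENT_FORMAT:
        raise IntegrityError(f"unsupported document format {doc.get('format')!r}")
    processes: dict[str, dict] = doc.get("processes", {})

    loaded: set[str] = set()

    def load_process(pid: str) -> str:
        if pid in loaded:
            return pid
        try:
            spec = processes[pid]
        except KeyError:
            raise IntegrityError(f"document references missing process {pid!r}") from None
        for dep in spec["inputs"].values():
            load_process(dep)
        new_id = store.upsert_process(spec["component"], spec["config"], spec["inputs"])
        if new_id != pid:
            raise IntegrityError(f"document process {pid!r} rehashed to {new_id!r}")
        loaded.add(pid)
        return pid

    for pid in processes:
        load_process(pid)

    tail: str | None = None
    for pid in doc.get("steps", []):
        tail = store.extend_list(tail, pid)
    if tail != doc.get("tail"):
        raise IntegrityError("document tail id does not match the reconstructed list")

    for pid, entry in doc.get("results", {}).items():
        data_id = None
        if entry["status"] == "ok" and "data" in entry:
            data_id = store.upsert_data(entry["data"]["type"], entry["data"]["value"])
        store.put_result(
            ResultRecord(
                process_id=pid,
                status=entry["status"],
                data_id=data_id,
                error=entry.get("error"),
                timestamp=entry["timestamp"],
                external=bool(entry.get("external", False)),
            )
        )
    return tail
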