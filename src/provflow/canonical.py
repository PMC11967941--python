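"""Canonical JSON serialization and content hashing.

Every record in the provenance store is identified by the SHA-256 digest of
its canonical serialization: UTF-8 JSON with lexicographically sorted keys
and minimal separators.  A record-type tag ("process:", "fpl:", "data:",
"result:", ...) is prefixed before hashing so that structurally identical
payloads in different tables can never collide.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any

__all__ = ["canonical_json", "content_hash", "CanonicalizationError"]


class CanonicalizationError(ValueError):
    """Raised when a value cannot be canonically serialized (e.g. NaN)."""


def canonical_json(value: Any) -> bytes:
    """Serialize *value* to canonical JSON bytes.

    Keys are sorted, separators are minimal, and non-finite floats are
    rejected: records that need to carry infinities (e.g. z-scores) must
    encode them explicitly (see :mod:`provflow.fixtures.genesets`).
    """
    try:
        text = json.dumps(
            value,
            sort_keys=True,
            separators=(",", ":"),
            ensure_ascii=False,
            allow_nan=False,
        )
    except (TypeError, ValueError) as exc:
        raise CanonicalizationError(f"value is not canonically serializable: {exc}") from exc
    return text.encode("utf-8")


def content_hash(tag: str, value: Any) -> str:
    """SHA-256 hex digest of ``tag + ":" + canonical_json(value)``.

    The tag provides domain separation between record types.
    """
    h = hashlib.sha256()
    h.update(tag.encode("utf-8"))
    h.update(b":")
    h.update(canonical_json(value))
    return h.hexdigest()
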