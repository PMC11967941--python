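"""Structured visualization descriptions (headless views).

A view in this engine does not render pixels; it returns a typed,
canonical-JSON-serializable description of the visualization (kind, data
series, labels) so that figure content is testable and exportable.
"""

from __future__ import annotations

from typing import Sequence

from ..canonical import canonical_json
from .genesets import encode_score

__all__ = ["VizSpec", "tissue_bar_view"]


class VizSpec(dict):
    """A visualization description: {"kind", "data", "labels", ...}.

    Plain dict subclass so values flow through codecs unchanged; the
    class exists to give views a nameable output type.
    """

    def to_bytes(self) -> bytes:
        return canonical_json(dict(self))


def tissue_bar_view(values: Sequence[tuple[str, float]]) -> VizSpec:
    """One bar per labelled value, order preserved.

    Infinite scores are encoded as explicit "inf"/"-inf" markers rather
    than dropped, so unbounded z-scores remain visible in the chart data.
    """
    values = list(values)
    if not values:
        raise ValueError("bar view requires at least one value")
    return VizSpec(
        kind="bar",
        labels=[label for label, _ in values],
        data=[encode_score(v) for _, v in values],
    )
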