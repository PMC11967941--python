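"""Gene sets, GMT libraries, set algebra, and overlap regions.

Gene symbols are uppercased on ingest and deduplicated preserving first
occurrence.  A scored (ranked) gene list is an ordered list of
``(symbol, score)`` pairs sorted by descending score with ties broken by
symbol; scores may be ±infinity (encoded as the strings ``"inf"`` /
``"-inf"`` in canonical JSON, matching how such screens print unbounded
z-scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GeneSet",
    "GeneSetLibrary",
    "GMTParseError",
    "parse_gmt",
    "write_gmt",
    "combine_sets",
    "sort_scored",
    "ranked_to_set",
    "overlap_regions",
    "encode_score",
    "decode_score",
]

MAX_OVERLAP_SETS = 16  # 2^16 - 1 candidate regions; combinatorial guard


class GMTParseError(ValueError):
    def __init__(self, line_number: int, message: str) -> None:
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _normalize_genes(genes: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for g in genes:
        g = g.strip().upper()
        if g:
            seen.setdefault(g)
    return tuple(seen)


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of uppercase gene symbols (first-occurrence ordered)."""

    label: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", _normalize_genes(self.genes))

    @property
    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.as_set


@dataclass(frozen=True)
class GeneSetLibrary:
    """Ordered (term, description, GeneSet) entries with unique terms."""

    entries: tuple[tuple[str, str, GeneSet], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        terms = [t for t, _, _ in self.entries]
        dupes = {t for t in terms if terms.count(t) > 1}
        if dupes:
            raise ValueError(f"duplicate terms in library: {sorted(dupes)}")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t, _, _ in self.entries)

    def sets(self) -> list[GeneSet]:
        return [s for _, _, s in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def with_entry(self, term: str, description: str, gene_set: GeneSet) -> "GeneSetLibrary":
        return GeneSetLibrary(self.entries + ((term, description, gene_set),))


# -- GMT I/O -----------------------------------------------------------


def parse_gmt(text: str) -> GeneSetLibrary:
    """Parse tab-separated GMT text: term, description, then gene symbols.

    Blank gene fields are dropped; genes are uppercased and deduplicated.
    A line with fewer than three fields is an error citing the line number.
    """
    entries = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise GMTParseError(lineno, f"expected ≥3 tab-separated fields, got {len(fields)}")
        term, description = fields[0].strip(), fields[1].strip()
        genes = _normalize_genes(fields[2:])
        if not genes:
            raise GMTParseError(lineno, "no non-blank gene symbols")
        entries.append((term, description, GeneSet(term, genes)))
    return GeneSetLibrary(tuple(entries))


def write_gmt(library: GeneSetLibrary) -> str:
    lines = [
        "\t".join([term, description, *gene_set.genes])
        for term, description, gene_set in library.entries
    ]
    return "\n".join(lines) + ("\n" if lines else "")


# -- set algebra -------------------------------------------------------


def combine_sets(
    sets: Sequence[GeneSet], mode: str = "union", k: int | None = None
) -> GeneSet:
    """Combine gene sets by union or consensus (genes in ≥ k sets).

    ``consensus`` defaults to majority: k = ⌈m/2⌉ over m sets.
    ``consensus(k=1)`` equals the union; k larger than the number of sets
    yields the empty set.  Output order is first appearance across inputs.
    """
    if not sets:
        raise ValueError("combine_sets requires at least one gene set")
    if mode not in ("union", "consensus"):
        raise ValueError(f"unknown mode {mode!r}")
    counts: dict[str, int] = {}
    for s in sets:
        for g in s.genes:
            counts[g] = counts.get(g, 0) + 1
    if mode == "union":
        threshold = 1
        label = "union"
    else:
        if k is None:
            k = math.ceil(len(sets) / 2)
        if k < 1:
            raise ValueError("consensus threshold k must be ≥ 1")
        threshold = k
        label = f"consensus(k={k})"
    genes = tuple(g for g in counts if counts[g] >= threshold)
    return GeneSet(label, genes)


# -- ranked lists ------------------------------------------------------


def sort_scored(scores: Iterable[tuple[str, float]]) -> list[tuple[str, float]]:
    """Canonical ranked order: score descending, ties by symbol ascending."""
    return sorted(scores, key=lambda gs: (-gs[1], gs[0]))


def ranked_to_set(scores: Sequence[tuple[str, float]], n: int) -> GeneSet:
    """Top-*n* genes of a ranked list as a gene set (n ≥ len → all genes)."""
    if n < 0:
        raise ValueError("cutoff n must be non-negative")
    ranked = sort_scored(scores)
    return GeneSet(f"top-{n}", tuple(g for g, _ in ranked[:n]))


# -- overlap regions ---------------------------------------------------


def overlap_regions(library: GeneSetLibrary) -> dict:
    """Counts of every non-empty membership pattern across the library's sets.

    The UpSet/SuperVenn-style decomposition: each gene in the union is
    counted in exactly one region (the exact subset of sets containing
    it), so region counts sum to the union size.  Returns a
    visualization-description dict (kind ``overlap-regions``).
    """
    sets = library.sets()
    if not 1 <= len(sets) <= MAX_OVERLAP_SETS:
        raise ValueError(
            f"overlap_regions supports 1..{MAX_OVERLAP_SETS} sets, got {len(sets)}"
        )
    terms = list(library.terms)
    membership: dict[tuple[str, ...], int] = {}
    union: set[str] = set()
    for s in sets:
        union |= s.as_set
    for gene in union:
        pattern = tuple(t for t, s in zip(terms, sets) if gene in s.as_set)
        membership[pattern] = membership.get(pattern, 0) + 1
    regions = [
        {"sets": list(pattern), "count": count}
        for pattern, count in sorted(membership.items())
    ]
    return {
        "kind": "overlap-regions",
        "labels": terms,
        "data": regions,
        "union_size": len(union),
    }


# -- score encoding ----------------------------------------------------


def encode_score(score: float) -> float | str:
    """Map ±infinity to the explicit strings "inf"/"-inf" for canonical JSON."""
    if math.isinf(score):
        return "inf" if score > 0 else "-inf"
    return float(score)


def decode_score(value: float | str) -> float:
    if value == "inf":
        return math.inf
    if value == "-inf":
        return -math.inf
    return float(value)
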