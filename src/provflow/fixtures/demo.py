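"""A canonical offline demonstration workflow.

Builds (and optionally executes) the end-to-end screening workflow used
throughout the documentation: a synthetic tumor-vs-background count
matrix is uploaded, genes are ranked by the z-score screen, the top 10
become a gene set, that set joins an uploaded GMT library, the library
is collapsed by consensus, and the set overlaps are computed as a
visualization description.
"""

from __future__ import annotations

from ..executor import ExecutionLog, Executor
from ..registry import Registry
from ..store import MemoryStore, Store
from .components import build_fixture_registry
from .screen import synth_counts, write_counts_tsv

__all__ = ["DEMO_GMT", "build_demo_workflow"]

DEMO_GMT = (
    "tumor_markers\tknown tumor-associated genes\tG00\tG01\tG05\tG07\n"
    "stress_response\tstress response panel\tG01\tG03\tG07\tG11\n"
)


def build_demo_workflow(
    seed: int = 7,
    n_genes: int = 60,
    n_case: int = 5,
    n_background: int = 10,
    planted: tuple[tuple[int, float], ...] = ((0, 50.0), (1, 50.0)),
    registry: Registry | None = None,
    store: Store | None = None,
    execute: bool = True,
    parallelism: int = 2,
):
    """Return ``(registry, store, tail, step_ids, log)`` for the demo workflow.

    Steps: upload_count_matrix → zscore_screen → ranked_cutoff(n=10) →
    upload_gmt → collect_sets → combine_library(consensus k=2) →
    overlap_view.
    """
    registry = registry or build_fixture_registry()
    store = store or MemoryStore(registry)
    matrix = synth_counts(seed, n_genes, n_case, n_background, planted)
    tsv = write_counts_tsv(matrix)

    p_upload = store.upsert_process("upload_count_matrix", {"tsv": tsv}, {})
    p_screen = store.upsert_process("zscore_screen", None, {"matrix": p_upload})
    p_cutoff = store.upsert_process("ranked_cutoff", {"n": 10}, {"scores": p_screen})
    p_gmt = store.upsert_process("upload_gmt", {"gmt": DEMO_GMT}, {})
    p_collect = store.upsert_process(
        "collect_sets", None, {"gene_set": p_cutoff, "library": p_gmt}
    )
    p_combine = store.upsert_process(
        "combine_library", {"mode": "consensus", "k": 2}, {"library": p_collect}
    )
    p_overlap = store.upsert_process("overlap_view", None, {"library": p_collect})

    steps = [p_upload, p_screen, p_cutoff, p_gmt, p_collect, p_combine, p_overlap]
    tail = None
    for pid in steps:
        tail = store.extend_list(tail, pid)

    log = ExecutionLog()
    if execute:
        Executor(registry, store, workers=parallelism, log=log).run_workflow(tail, parallelism)
    return registry, store, tail, steps, log
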