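"""Fixture semantic types and components for offline end-to-end workflows.

Builds a registry wiring the gene-set and screening operations into
engine components: upload prompts inject GMT libraries and count
matrices, resolvers run the z-score screen and set algebra, and views
produce bar-chart and overlap-region descriptions.
"""

from __future__ import annotations

from typing import Any, Mapping

import pandas as pd

from ..registry import Component, Registry, SemanticType
from .genesets import (
    GeneSet,
    GeneSetLibrary,
    combine_sets,
    decode_score,
    encode_score,
    overlap_regions,
    parse_gmt,
    ranked_to_set,
)
from .screen import CountMatrix, parse_counts_tsv, zscore_screen
from .views import VizSpec, tissue_bar_view

__all__ = ["build_fixture_registry", "TYPE_IDS"]

TYPE_IDS = ("gene_set", "gene_set_library", "scored_genes", "count_matrix", "viz_spec")

_CITATIONS = {
    "gmt-format": (
        "Liberzon A, et al. Molecular signatures database (MSigDB) 3.0. "
        "Bioinformatics. 2011;27(12):1739-40."
    ),
    "upset": (
        "Lex A, et al. UpSet: Visualization of intersecting sets. "
        "IEEE Trans Vis Comput Graph. 2014;20(12):1983-92."
    ),
    "target-screen": (
        "Marino GB, et al. TargetRanger: a web server to identify candidate "
        "targets from gene expression data. Nucleic Acids Res. 2023;51(W1):W213-24."
    ),
}


# -- codecs ------------------------------------------------------------


def _encode_gene_set(v: GeneSet) -> dict:
    return {"label": v.label, "genes": list(v.genes)}


def _decode_gene_set(j: dict) -> GeneSet:
    return GeneSet(j["label"], tuple(j["genes"]))


def _encode_library(v: GeneSetLibrary) -> dict:
    return {"entries": [[t, d, _encode_gene_set(s)] for t, d, s in v.entries]}


def _decode_library(j: dict) -> GeneSetLibrary:
    return GeneSetLibrary(tuple((t, d, _decode_gene_set(s)) for t, d, s in j["entries"]))


def _encode_scored(v: list[tuple[str, float]]) -> list:
    return [[g, encode_score(s)] for g, s in v]


def _decode_scored(j: list) -> list[tuple[str, float]]:
    return [(g, decode_score(s)) for g, s in j]


def _encode_matrix(v: CountMatrix) -> dict:
    return {
        "genes": [str(g) for g in v.counts.index],
        "samples": [str(s) for s in v.counts.columns],
        "counts": [[int(c) for c in row] for row in v.counts.to_numpy()],
        "labels": dict(v.sample_labels),
    }


def _decode_matrix(j: dict) -> CountMatrix:
    df = pd.DataFrame(j["counts"], index=j["genes"], columns=j["samples"])
    return CountMatrix(df, j["labels"])


def _encode_viz(v: Mapping[str, Any]) -> dict:
    return dict(v)


def _decode_viz(j: dict) -> VizSpec:
    return VizSpec(j)


# -- run contracts -----------------------------------------------------


def _run_upload_gmt(inputs: Mapping[str, Any], config: Any) -> GeneSetLibrary:
    return parse_gmt(config["gmt"])


def _run_upload_counts(inputs: Mapping[str, Any], config: Any) -> CountMatrix:
    return parse_counts_tsv(config["tsv"])


def _run_screen(inputs: Mapping[str, Any], config: Any) -> list[tuple[str, float]]:
    matrix: CountMatrix = inputs["matrix"]
    case = matrix.samples_with_label("case")
    background = matrix.samples_with_label("background")
    return zscore_screen(matrix, case, background)


def _run_cutoff(inputs: Mapping[str, Any], config: Any) -> GeneSet:
    return ranked_to_set(inputs["scores"], config["n"])


def _run_collect(inputs: Mapping[str, Any], config: Any) -> GeneSetLibrary:
    gene_set: GeneSet = inputs["gene_set"]
    library: GeneSetLibrary = inputs["library"]
    return library.with_entry(gene_set.label, "", gene_set)


def _run_combine(inputs: Mapping[str, Any], config: Any) -> GeneSet:
    library: GeneSetLibrary = inputs["library"]
    return combine_sets(library.sets(), mode=config["mode"], k=config.get("k"))


def _run_overlap_view(inputs: Mapping[str, Any], config: Any) -> VizSpec:
    return VizSpec(overlap_regions(inputs["library"]))


def _run_bar_view(inputs: Mapping[str, Any], config: Any) -> VizSpec:
    return tissue_bar_view(inputs["scores"][:10])


# -- registry ----------------------------------------------------------


def build_fixture_registry() -> Registry:
    """Registry with the offline gene-set / screening component library."""
    reg = Registry()
    reg.register_type(SemanticType(
        "gene_set", "Gene set", "A labelled set of gene symbols",
        encode=_encode_gene_set, decode=_decode_gene_set,
    ))
    reg.register_type(SemanticType(
        "gene_set_library", "Gene set library",
        "An ordered collection of named gene sets (GMT)",
        encode=_encode_library, decode=_decode_library,
    ))
    reg.register_type(SemanticType(
        "scored_genes", "Ranked gene list",
        "Gene symbols ranked by a numeric score (possibly infinite)",
        encode=_encode_scored, decode=_decode_scored,
    ))
    reg.register_type(SemanticType(
        "count_matrix", "Gene count matrix",
        "Gene-by-sample expression counts with sample group labels",
        encode=_encode_matrix, decode=_decode_matrix,
    ))
    reg.register_type(SemanticType(
        "viz_spec", "Visualization",
        "A structured visualization description",
        encode=_encode_viz, decode=_decode_viz,
    ))

    reg.register_component(Component(
        id="upload_gmt", kind="prompt",
        label="Upload gene set library",
        description="Upload a GMT file of gene sets for analysis",
        inputs={}, output="gene_set_library",
        config_schema={
            "type": "object",
            "properties": {"gmt": {"type": "string"}},
            "required": ["gmt"],
            "additionalProperties": False,
        },
        run=_run_upload_gmt,
        story="A gene set library was uploaded in GMT format.",
        citations={"gmt-format": _CITATIONS["gmt-format"]},
        authors=("Ada Example",), license="CC-BY-4.0", version="1.0.0",
    ))
    reg.register_component(Component(
        id="upload_count_matrix", kind="prompt",
        label="Upload count matrix",
        description="Upload a tab-separated gene expression count matrix "
                    "with case and background sample annotations",
        inputs={}, output="count_matrix",
        config_schema={
            "type": "object",
            "properties": {"tsv": {"type": "string"}},
            "required": ["tsv"],
            "additionalProperties": False,
        },
        run=_run_upload_counts,
        story="A gene expression count matrix with annotated case and "
              "background samples was uploaded.",
        authors=("Ada Example",), license="CC-BY-4.0", version="1.0.0",
    ))
    reg.register_component(Component(
        id="zscore_screen", kind="resolver",
        label="Case vs background z-score screen",
        description="Rank genes highly expressed in the case samples but "
                    "lowly expressed across the background panel",
        inputs={"matrix": "count_matrix"}, output="scored_genes",
        run=_run_screen,
        story="Genes were ranked by the z-score of their mean expression in "
              "the case samples against the background sample distribution.",
        citations={"target-screen": _CITATIONS["target-screen"]},
        authors=("Ada Example", "Grace Fixture"), license="CC-BY-4.0", version="1.1.0",
    ))
    reg.register_component(Component(
        id="ranked_cutoff", kind="prompt",
        label="Ranked list cutoff",
        description="Turn a ranked gene list into a gene set by choosing a cutoff",
        inputs={"scores": "scored_genes"}, output="gene_set",
        config_schema={
            "type": "object",
            "properties": {"n": {"type": "integer", "minimum": 0}},
            "required": ["n"],
            "additionalProperties": False,
        },
        run=_run_cutoff,
        story="The top {n} genes of the ranked list were selected as a gene set.",
        authors=("Grace Fixture",), license="CC-BY-4.0", version="1.0.0",
    ))
    reg.register_component(Component(
        id="collect_sets", kind="resolver",
        label="Add gene set to library",
        description="Append a gene set to a gene set library as a new entry",
        inputs={"gene_set": "gene_set", "library": "gene_set_library"},
        output="gene_set_library",
        run=_run_collect,
        story="The gene set was added to the gene set library.",
        authors=("Grace Fixture",), license="CC-BY-4.0", version="1.0.0",
    ))
    reg.register_component(Component(
        id="combine_library", kind="prompt",
        label="Combine gene sets",
        description="Collapse a gene set library into a single gene set by a "
                    "union or consensus set operation",
        inputs={"library": "gene_set_library"}, output="gene_set",
        config_schema={
            "type": "object",
            "properties": {
                "mode": {"type": "string", "enum": ["union", "consensus"]},
                "k": {"type": "integer", "minimum": 1},
            },
            "required": ["mode"],
            "additionalProperties": False,
        },
        run=_run_combine,
        story="The gene sets in the library were combined with a {mode} set operation.",
        citations={"gmt-format": _CITATIONS["gmt-format"]},
        authors=("Ada Example",), license="CC-BY-4.0", version="1.0.0",
    ))
    reg.register_component(Component(
        id="overlap_view", kind="view",
        label="Set overlap regions",
        description="Visualize the overlap between the gene sets of a library "
                    "as UpSet-style membership regions",
        inputs={"library": "gene_set_library"}, output="viz_spec",
        run=_run_overlap_view,
        story="The overlap between the gene sets was visualized as "
              "membership regions.",
        citations={"upset": _CITATIONS["upset"], "gmt-format": _CITATIONS["gmt-format"]},
        authors=("Grace Fixture",), license="CC-BY-4.0", version="1.0.0",
    ))
    reg.register_component(Component(
        id="bar_view", kind="view",
        label="Top genes bar chart",
        description="Bar chart of the top ranked genes and their scores",
        inputs={"scores": "scored_genes"}, output="viz_spec",
        run=_run_bar_view,
        story="The top ranked genes were visualized as a bar chart.",
        authors=("Ada Example",), license="CC-BY-4.0", version="1.0.0",
    ))
    return reg
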