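"""Count matrices and the tumor-vs-background z-score target screen.

The screen ranks genes by how specifically they are expressed in a group
of case (e.g. tumor) samples relative to a background panel (e.g. normal
tissues):

    z_g = (mean_case(g) − mean_background(g)) / sd_background(g)

with the sample standard deviation (ddof = 1) over the background.  When
the background variance is zero the z-score is ±infinity by convention
(+inf if the case mean exceeds the constant background, −inf if below,
0 if equal) — genes absent from every background sample but expressed in
the tumor are exactly the most interesting targets, and screens of this
kind print them as "inf".

A seeded negative-binomial generator provides synthetic matrices with
planted case-specific over-expression for end-to-end testing.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genesets import sort_scored

__all__ = ["CountMatrix", "zscore_screen", "synth_counts", "parse_counts_tsv", "write_counts_tsv"]


@dataclass(frozen=True)
class CountMatrix:
    """Gene-by-sample non-negative integer counts with sample group labels.

    ``counts`` is a pandas DataFrame (rows: unique gene symbols; columns:
    unique sample ids).  ``sample_labels`` maps sample ids to free-form
    group labels such as ``"case"`` / ``"background"``.
    """

    counts: pd.DataFrame
    sample_labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("gene and sample names must be unique")
        if (df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(self.sample_labels) - set(df.columns)
        if unknown:
            raise ValueError(f"labels for unknown samples: {sorted(unknown)}")

    def samples_with_label(self, label: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_labels.get(s) == label]


def zscore_screen(
    matrix: CountMatrix,
    case_samples: Sequence[str],
    background_samples: Sequence[str],
) -> list[tuple[str, float]]:
    """Rank genes by case-vs-background z-score (descending, ties by symbol).

    Requires non-empty, disjoint sample groups (background ≥ 2 samples so
    the sample standard deviation is defined).
    """
    case = list(case_samples)
    background = list(background_samples)
    if not case or not background:
        raise ValueError("case and background sample groups must be non-empty")
    if set(case) & set(background):
        raise ValueError("case and background sample groups must be disjoint")
    if len(background) < 2:
        raise ValueError("background needs ≥2 samples for a sample standard deviation")
    missing = (set(case) | set(background)) - set(matrix.counts.columns)
    if missing:
        raise ValueError(f"unknown sample ids: {sorted(missing)}")

    case_mean = matrix.counts[case].mean(axis=1)
    bg = matrix.counts[background]
    bg_mean = bg.mean(axis=1)
    bg_sd = bg.std(axis=1, ddof=1)

    scores = []
    for gene in matrix.counts.index:
        diff = float(case_mean[gene] - bg_mean[gene])
        sd = float(bg_sd[gene])
        if sd == 0.0:
            z = math.inf if diff > 0 else (-math.inf if diff < 0 else 0.0)
        else:
            z = diff / sd
        scores.append((str(gene), z))
    return sort_scored(scores)


def synth_counts(
    seed: int,
    n_genes: int = 200,
    n_case: int = 5,
    n_background: int = 20,
    planted: Sequence[tuple[int, float]] = (),
) -> CountMatrix:
    """Seeded synthetic count matrix with planted case-specific signal.

    Baseline counts are negative-binomial: per-gene mean μ_g drawn
    log-normally (median 100, σ_log = 1) and dispersion r = 10 shared
    across genes, i.e. NB(r, p) with p = r / (r + μ).  Planted genes have
    their mean multiplied by ``fold`` in case samples only.  The same seed
    always yields the identical matrix.
    """
    if n_genes < 1 or n_case < 1 or n_background < 1:
        raise ValueError("dimensions must be positive")
    for idx, fold in planted:
        if not 0 <= idx < n_genes:
            raise ValueError(f"planted gene index {idx} out of range")
        if fold <= 0:
            raise ValueError("planted fold changes must be positive")

    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(np.log(100.0), 1.0, size=n_genes))
    r = 10.0
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    case_ids = [f"case_{i}" for i in range(n_case)]
    bg_ids = [f"bg_{i}" for i in range(n_background)]

    def draw(mean: np.ndarray, n_samples: int) -> np.ndarray:
        p = r / (r + mean)
        return rng.negative_binomial(r, p[:, None], size=(n_genes, n_samples))

    mu_case = mu.copy()
    for idx, fold in planted:
        mu_case[idx] *= fold
    counts = np.concatenate([draw(mu_case, n_case), draw(mu, n_background)], axis=1)
    df = pd.DataFrame(counts, index=genes, columns=case_ids + bg_ids)
    labels = {s: "case" for s in case_ids} | {s: "background" for s in bg_ids}
    return CountMatrix(df, labels)


# -- TSV dialect -------------------------------------------------------
# First column: gene symbol; header row: sample ids; optional second
# header line "#labels" carrying the per-sample group labels.


def parse_counts_tsv(text: str) -> CountMatrix:
    lines = text.splitlines()
    labels: dict[str, str] = {}
    body = []
    header: list[str] | None = None
    for line in lines:
        if header is None:
            header = line.rstrip("\n").split("\t")
            continue
        if line.startswith("#labels"):
            values = line.rstrip("\n").split("\t")[1:]
            labels = dict(zip(header[1:], values))
            continue
        if line.strip():
            body.append(line)
    if header is None or not body:
        raise ValueError("empty count matrix")
    df = pd.read_csv(io.StringIO("\n".join(["\t".join(header), *body])), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return CountMatrix(df, labels)


def write_counts_tsv(matrix: CountMatrix) -> str:
    buf = io.StringIO()
    cols = list(matrix.counts.columns)
    buf.write("\t".join(["gene", *cols]) + "\n")
    if matrix.sample_labels:
        buf.write("\t".join(["#labels", *[matrix.sample_labels.get(c, "") for c in cols]]) + "\n")
    for gene, row in matrix.counts.iterrows():
        buf.write("\t".join([str(gene), *[str(int(v)) for v in row]]) + "\n")
    return buf.getvalue()
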