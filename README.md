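# provflow

A headless workflow engine for bioinformatics analyses that records
*complete, content-addressed provenance* for every step. Workflows are
assembled from typed components — **prompts** (user decisions captured
as JSON configuration), **resolvers** (pure functions over typed
values), and **views** (structured visualization descriptions) — whose
semantic input/output types form a graph that the engine queries to
enumerate which steps can legally come next. Every executed workflow is
stored in a fully persistent, content-addressed database (processes,
list nodes, results, data blobs, all identified by the SHA-256 of their
canonical serialization), which gives automatic deduplication, shared
workflow prefixes, git-style rebase of interior steps, and memoized
re-execution for free. Stored workflows export to CWL v1.2, IEEE 2791
BioCompute Objects, Workflow RO-Crates, and publication-style methods
reports assembled by stacking each step's parameterized story sentence
with numbered citations.

It is aimed at tool builders who want reproducible, publishable
workflow provenance without a web stack: the library is the product,
and a thin `provflow` CLI wraps it for shell use. An offline fixture
library (GMT gene-set handling, set algebra, ranked-list cutoffs,
UpSet-style overlap regions, and a tumor-vs-background z-score target
screen with synthetic count matrices) exercises the engine end to end.

## The core ideas

- **Content addressing.** A process record is
  `(component, config, inputs)`; its id is
  `sha256("process:" + canonical_json(record))`. Identical steps built
  by different users, or the same graph built in different orders,
  collapse to one row with one id.
- **Fully persistent lists.** Step order is a linked list resolved from
  the id of its last node; extending never mutates, and two workflows
  sharing a prefix share its nodes physically.
- **Rebase.** Replacing an interior step regenerates only that step and
  its transitive dependents (with rewritten input references); all
  other ids — and their cached results — survive.
- **Memoized execution.** A worker pool resolves results on demand;
  each process runs at most once per store, and the result map is
  byte-identical at any parallelism.
- **Z-score screen.** Genes are ranked by
  `z = (mean_case − mean_bg) / sd_bg` (sample sd, ddof = 1), with
  `z = ±inf` when the background variance is zero — genes silent across
  the background but expressed in the case samples are the most
  interesting targets and sort to the top.

## Worked example

The bundled demo builds and runs a seven-step screening workflow on a
seeded synthetic count matrix (40 genes; 3 case vs 6 background
samples; genes G00 and G01 planted at fold 50):

```python
from provflow.fixtures import build_demo_workflow
from provflow.exporters import build_report

registry, store, tail, steps, log = build_demo_workflow(seed=7, n_genes=40,
                                                        n_case=3, n_background=6)
scores = store.get_data(store.get_result(steps[1]).data_id).value
print(scores[:3])
consensus = store.get_data(store.get_result(steps[5]).data_id).value
print(consensus["genes"])
print(build_report(registry, store, tail).methods)
```

prints (seed 7):

```
[['G01', 226.14913659284085], ['G00', 191.94053245329243], ['G17', 3.689784826162325]]
['G00', 'G01', 'G05', 'G07']
A gene expression count matrix with annotated case and background samples was
uploaded. Genes were ranked by the z-score of their mean expression in the case
samples against the background sample distribution. [1] The top 10 genes of the
ranked list were selected as a gene set. A gene set library was uploaded in GMT
format. [2] The gene set was added to the gene set library. The gene sets in the
library were combined with a consensus set operation. [2] The overlap between
the gene sets was visualized as membership regions. [2,3]
```

The two planted genes dominate the ranking (z ≈ 226 and 192 against
z ≈ 3.7 for the best unplanted gene), survive the top-10 cutoff, and
appear in the consensus with the uploaded marker sets; the stacked
story sentences form the methods paragraph with deduplicated numbered
citations.

The same pipeline runs from the shell: `provflow build` turns a
declarative steps file into a self-contained workflow document,
`provflow run` executes it (re-running performs zero executions — every
step is memoized), and `provflow export --format {cwl,bco,rocrate,report}`
writes the exchange formats. `provflow next` and `provflow suggest`
enumerate and rank compatible next steps; `provflow invoke` runs a
single component on JSON files and is the execution target of the
exported CWL tools.

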