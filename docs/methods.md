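# Methods

## The model

provflow is a headless engine for constructing, executing, and
publishing typed bioinformatics workflows. Three ideas carry the design:

1. **Typed components.** A workflow building block (*component*) is a
   prompt (captures a user decision as a JSON configuration and emits a
   value; with no inputs it injects the workflow's starting value), a
   resolver (a pure function from typed inputs to one typed output), or
   a view (maps a value to a structured visualization description).
   Inputs and outputs are *semantic types* — named data kinds with
   codecs to canonical JSON — so "a gene count matrix" is distinguishable
   from "a file". Types and components form a directed graph that is a
   pure function of the registry; enumerating the components whose input
   types are all available gives the legal next steps of a partial
   workflow.

2. **Content-addressed, fully persistent provenance.** Executed
   workflows live in four tables: processes (component + config +
   back-references to input processes), fully persistent list nodes
   (step order; a workflow is the id of its last node and shared
   prefixes are physically shared), results (one per process, with an
   execution timestamp), and data blobs (canonical JSON). Every id is
   the SHA-256 of the record's canonical serialization, so identical
   content dedupes to one row regardless of insertion order, and two
   users building the same analysis converge on the same ids. Editing an
   interior step is a git-style rebase: only the target and its
   transitive dependents are regenerated; everything else — including
   already-computed results — is reused.

3. **Memoized execution.** Results are resolved on demand through a
   FIFO ready-queue over an in-process worker pool. A process executes
   at most once per store lifetime; purity of the run contracts makes
   this sound, and content addressing makes the final result map
   independent of the parallelism level. Errors are stored and memoized
   like successes (status `error`); dependents receive a
   dependency-failure result without running; nothing is retried unless
   explicitly forced.

Exports translate a stored workflow into CWL v1.2 (one CommandLineTool
per component wrapping the engine's `invoke` CLI; prompt configurations
become workflow-level inputs bound in the job file), an IEEE 2791
BioCompute Object, a Workflow RO-Crate, and a methods report that stacks
each step's parameterized story sentence with numbered, deduplicated
citations. Report copyediting is a pluggable post-processor with an
identity default.

## Numerical and encoding conventions

- Canonical JSON: UTF-8, lexicographically sorted keys, minimal
  separators; NaN and bare infinities are rejected. Record hashes are
  SHA-256 over a record-type tag (`process:`, `fpl:`, `data:`, …) plus
  the canonical bytes; the tag prevents cross-table collisions.
- Timestamps are result metadata and never enter a content hash —
  otherwise re-execution would break deduplication.
- The BCO etag is the SHA-256 of the canonical document with the etag
  field removed, so recipients can recompute it. Created/modified times
  are taken from stored result records, making exports of an executed
  workflow byte-deterministic.
- Infinite scores are encoded as the explicit strings `"inf"` /
  `"-inf"` in JSON payloads and visualization data rather than dropped.
- Next-step ordering is (prompt < resolver < view, label, id); the
  suggestion baseline scores candidates by
  `|tokens(text) ∩ tokens(label+description)| / (1 + |tokens(label+description)|)`
  with case-folded alphanumeric tokens, ties broken by label then id. It
  is a deterministic lexical stand-in behind the same contract an
  LLM-backed chooser would implement.
- The empty workflow is the `null` list tail.

## The z-score screen

The fixture screen ranks genes expressed in case (e.g. tumor) samples
but quiet across a background panel:

    z_g = (mean_case(g) − mean_background(g)) / sd_background(g)

with the sample standard deviation (ddof = 1) over background samples
(hence ≥ 2 background samples are required). When the background
variance is zero the convention is z = +∞ if the case mean exceeds the
constant background, −∞ if below, and 0 if equal: a gene silent in
every background sample but expressed in the tumor is maximally
specific, and such screens print these as `inf`. Output is sorted by
descending score with ties broken by symbol, so rankings are total and
reproducible. No filtering or library-size normalization is applied
before scoring; the screen is the minimal contract on raw counts, and
callers who need normalization should apply it upstream.

Consensus set combination defaults to majority (k = ⌈m/2⌉ over m sets)
when no threshold is given; `consensus(k=1)` equals the union. Overlap
regions assign each gene of the union to exactly one membership
pattern, so region counts always sum to the union size; the computation
refuses more than 16 sets (2^16 − 1 candidate regions).

## Synthetic count matrices

`synth_counts` emulates a bulk RNA-seq screening input: per-gene means
μ_g ~ LogNormal(log 100, 1) (median 100 counts, a realistic skew across
genes) and negative-binomial counts with shared dispersion r = 10
(moderate biological overdispersion), case and background samples drawn
independently. Planted genes have their mean multiplied by the fold
change in case samples only. Defaults (5 case vs 10–20 background
samples, 60–200 genes, fold 50 for planted targets) are sized for a
desk-scale screen. The generator does **not** emulate library-size
differences, gene–gene correlation, batch effects, or tissue-specific
expression structure — so passing recovery tests show the screen's
ranking behaves correctly under clean overdispersed counts, not that it
is robust to real-data confounding.

## Testing and validation choices

- Oracles are independent re-computations: brute-force applicability
  filters for next-step enumeration, a recursive dependency traversal
  for rebase conservation, direct hashlib/json re-hashing for content
  ids, and hand-computed examples for the set algebra and z-scores.
- CWL bundles are checked structurally (document classes, step wiring,
  metadata completeness, isomorphism of the step graph to the process
  dependency graph) and dynamically: a minimal in-repo runner executes
  the exported CommandLineTools via subprocess exactly as their command
  lines specify and the outputs must equal the engine's stored payloads
  byte-for-byte.
- BCO documents validate against a bundled structural schema authored
  for this package as a rendering of the IEEE 2791-2020 object model
  (`ieee2791_schema_synthetic`), via a small generic JSON-Schema
  validator (`jsonschema_lite`) that also enforces prompt configuration
  schemas.
- RO-Crate metadata is hand-written JSON-LD checked against the
  Workflow RO-Crate profile structure (metadata descriptor, root
  dataset, main workflow entity, resolvable author/license entities).
- Problem sizes in the default test run (randomized registries of 100
  components × 20 types, 1,000-operation store workloads, DAGs of ≤ 12
  steps, 20-seed recovery runs, a 7-step demo workflow) keep the whole
  suite around ten seconds while exercising every code path at the
  scale the properties are stated.

## Known limitations

- The store keeps data blobs and files inline (memory or a single
  SQLite file); no S3/remote backends, no multi-user concerns.
- Workers are in-process threads; cross-machine queues are out of
  scope, though the queue contract (FIFO ready tasks, memoized results)
  is transport-independent.
- The CWL runner handles exactly the document subset the exporter
  emits; it is a round-trip harness, not a general CWL implementation.
- No component in the fixture library calls external services; the
  `external` result flag exists for components that do, marking their
  results as snapshots of an evolving source rather than pure function
  values.
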