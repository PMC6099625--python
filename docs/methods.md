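# Methods

## Problem model

A corpus is a list of files `F_0 … F_{m−1}`, each with a size in characters;
`n` worker processes (ranks) must each receive a disjoint subset. Workers
are homogeneous and non-preemptive; a file is processed by one worker from
start to finish (file-level granularity, because annotators pay a large
one-time per-process initialization that per-sentence splitting would
multiply). Scheduling is static: the partition is fixed before execution,
so no inter-worker communication or work stealing is needed, and the run
completes when the slowest rank finishes (the makespan).

### Workload model

Per-file processing cost is modelled as affine in size:
`t(s) = a + b·s`, with `a ≥ 0` (per-file overhead) and `b > 0` (seconds per
character or per MB; the model records its unit, and 1 MB is taken as 10⁶
characters when converting). The fit is unweighted ordinary least squares —
timing data sets here are tiny (a handful of sizes) and carry no variance
information, so weighting would be invented. A negative fitted intercept is
clamped to zero since a zero-size file cannot have negative cost. The
bundled serial benchmark (four points, 1–8 MB) fits to
`b ≈ 1128.5 s/MB`, `a ≈ 848 s`, with all four residuals under 10%.

Schedulers consume per-file costs; when no timing model is supplied they use
raw character counts (identity model). Rank order produced by the sorting
strategies is invariant to a positive affine transform of the costs except
through the intercept, so the identity default changes nothing when `a = 0`.
"Current load" in the Short-Board greedy is cumulative predicted cost, not
file count.

### Strategies

- **modulo**: rank `P mod n` by list position; a seeded Fisher–Yates shuffle
  (NumPy `default_rng.permutation`) optionally randomizes the order first,
  replacing the irreproducible "arbitrary directory order" randomness of
  real deployments with a reproducible one.
- **round_robin**: sort by cost descending, deal serpentine passes starting
  left-to-right on rank 0 (the starting direction is a convention; the
  passes are symmetric under rank relabelling).
- **short_board**: LPT greedy. Deterministic tie-breaks — equal costs by
  file id ascending, equal loads by lowest rank — so assignments are
  byte-reproducible. Classical results apply: makespan(LPT) ≤
  (4/3 − 1/(3n)) · OPT (Graham), verified in the tests against an exact
  oracle.

### Metrics

`LBE = AET / MET` over per-rank execution times; per-rank time in the
engine is per-plugin initialization plus per-file processing. The mean is
computed with compensated summation and clamped at the maximum so perfectly
balanced runs report exactly 1 (the mean can exceed the max by one ulp in
plain floating point). Reporting layers round to two decimals.

### Exact oracle

`optimal_makespan` enumerates partitions depth-first with two prunings:
symmetry (a file may open at most one previously empty rank, and ranks with
identical current loads are interchangeable) and bound (branches whose
current maximum already meets the incumbent are cut). Capped by default at
14 files and 4 ranks; above the cap it refuses and points to the simulator.

## Formats

**PubTator**: `<id>|t|title`, optional `<id>|a|body`, then 5- or 6-field
tab-separated annotation lines, blank line between blocks; UTF-8, Unix
newlines. Annotation offsets are 0-based end-exclusive character (not byte)
offsets into the composite text `title + " " + body` (title alone when the
body is empty) — one separator character between title and abstract,
matching common PubTator practice. Written output always emits 6 fields
(empty concept id allowed). Newlines inside titles/bodies are structurally
unrepresentable, so the NXML extractor collapses all whitespace runs to
single spaces. Parsing is strict by default (scheduling needs trustworthy
sizes); lenient mode skips malformed blocks with a logged warning. Every
read and write re-validates that each mention equals the substring its span
indexes.

**JATS/NXML**: title from `article-title`, id from the `pub-id-type="pmid"`
`article-id` (caller fallback otherwise), body from the flattened abstract,
optionally followed by body paragraphs joined with single spaces when full
text is requested (full text extends, not replaces, the abstract line). Tag
matching is namespace-agnostic since JATS appears both with and without a
default namespace in the wild.

## Engine

Static scatter–gather: rank 0 sizes the corpus (lenient sizing — a file that
fails to parse is sized by raw length and the parse error surfaces later as
that file's failure), computes the assignment, and dispatches; each worker
builds and initializes every plugin exactly once, annotates its files,
merges per-plugin annotations (duplicates collapsed on span+type+concept),
and writes one PubTator output per input. Failures are isolated per file,
recorded in the timing log, and optionally escalated in strict mode — on a
large corpus one corrupt file should not void hours of work.

Backends: `serial` (in-process loop over ranks — the timing reference),
`local` (one forked OS process per rank; fork so the plugin registry is
inherited without pickling), `mpi` (scatter/gather over mpi4py when
installed; functionally identical contract, untested where no MPI stack
exists). The invariant across all of them: the set of
(doc, span, type, concept) annotation tuples is identical for every
backend, strategy, and worker count.

Per-plugin `max_procs_per_node` caps (memory-bound tools allow only a few
instances per node) are validated as warnings only — the engine cannot
portably observe physical node placement; the launcher owns placement.
Timings use the monotonic clock and are logged, never asserted against.

## Simulator

Each rank's simulated time is `init_cost + Σ predicted file costs`; with
zero init and the identity model the simulated MET equals the scheduling
makespan exactly, which anchors the simulator to the scheduler in tests.
Initialization is one constant per worker (summed over plugins); it
reproduces the scaling plateau — as `n` grows, init dominates, MET stops
falling, and LBE drifts toward 1. The simulator is pure arithmetic; a full
strategy-comparison table over dozens of process counts runs in
milliseconds. It does not model memory contention, I/O bandwidth, or
interconnect effects, so absolute wall-clock predictions are out of scope —
only comparisons between strategies on the same cost vector are meaningful.

## Synthetic corpora

`generate_corpus` draws i.i.d. integer file sizes:

| distribution | defaults | emulates |
|---|---|---|
| uniform | low 2 000, high 40 000 chars | mildly varied abstracts |
| lognormal | log-mean 9.2, log-sd 1.0 (median ≈ 10 k chars) | abstract/full-text mix |
| pareto | tail index α = 1.2, scale 1 000 chars | a few extremely long files among many short ones |
| two_point | 1 000 vs 100 000 chars, 5% large | worst-case bimodality |

The pareto default α = 1.2 gives infinite variance — the regime where
size-blind distribution visibly fails and the strategy ranking
(short_board ≥ round_robin ≥ modulo in mean LBE) separates cleanly.
`materialize_corpus` writes PubTator files of exactly the drawn sizes,
filled with random word-like tokens plus known gene/disease/mutation
mentions (15% of tokens) so the demo taggers produce non-empty output;
synthetic text has none of real text's linguistic structure, so passing
pipeline tests demonstrates plumbing and scheduling correctness, not NER
quality.

The demonstration plugins (a regex tagger for protein substitutions like
`V600E` and HGVS-style `c.123A>G` changes; case-insensitive longest-match
dictionary taggers over ~20-entry gene/disease fixture lexica) are pure
functions of the document — deliberately trivial, since real NER tools are
treated as black-box plugins.

## Scales used in checks

Quantitative checks run at desk scale, chosen as the smallest sizes at
which the statistical properties are stable across seeds: 500 random
instances within the exact-oracle cap for the LPT bound; 50-seed batches of
200-file pareto corpora for the strategy ranking; a 50-document corpus for
cross-backend annotation identity; 200 generated corpora for the format
round-trip. Benchmark-scale absolute times (thousands of seconds per rank,
corpora of tens of thousands of articles) enter only through the bundled
timing tables, which are inputs to the metric computations, not
measurements this package can reproduce.

## Known limitations

- The cost proxy ignores per-plugin heterogeneity: different annotators have
  very different slopes, and the engine supports one `WorkloadModel` per
  run, not a joint multi-plugin fit.
- Static scheduling cannot react to cost-model error; a file whose true cost
  is far off its prediction still skews the run.
- The MPI backend is contract-complete but exercised only where an MPI
  stack is available; serial and local backends carry the test burden.
- Dynamic work stealing, multi-resource bin packing (memory + CPU), and
  per-sentence parallelism are out of scope by design.
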