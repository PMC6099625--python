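"""Execution engine: run annotation plugins over an assigned corpus.

Rank 0 plans (computes the static Assignment), workers execute their own
file lists independently, rank 0 gathers timing logs and merged outputs —
a static scatter–gather contract with no inter-worker communication during
processing, which is sound because input articles are independent.

Backends:

- ``serial``  — all ranks executed in turn in the calling process.
- ``local``   — one OS process per rank via :mod:`multiprocessing`.
- ``mpi``     — one MPI rank per worker (requires mpi4py; optional).

Whatever the backend, strategy, or worker count, the set of emitted
annotations is identical; only timing attribution changes.
"""

from __future__ import annotations

import multiprocessing as mp
import time
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Callable, Mapping, Sequence

from .corpus import Corpus, WorkloadModel, measure_corpus
from .pubtator import AnnotatedDocument, merge_annotations, read_pubtator, write_pubtator
from .scheduling import Assignment, RunMetrics, assign, lbe

__all__ = [
    "PluginSpec",
    "TimeLog",
    "register_plugin",
    "registered_plugins",
    "clear_registry",
    "run",
    "evaluate",
    "RunReport",
]


@dataclass(frozen=True)
class PluginSpec:
    """Metadata for a registered annotator.

    ``max_procs_per_node`` is the per-node concurrency cap imposed by the
    tool's memory footprint (e.g. a gene normalizer loading a multi-GB
    dictionary may allow only a handful of instances per node).  The engine
    cannot observe physical node placement portably, so the cap is enforced
    as a warning; the launcher remains responsible for placement.
    """

    name: str
    init_cost_hint: float = 0.0
    max_procs_per_node: int = 1_000_000
    entity_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("plugin name must be non-empty")
        if self.init_cost_hint < 0:
            raise ValueError("init_cost_hint must be >= 0")
        if self.max_procs_per_node < 1:
            raise ValueError("max_procs_per_node must be >= 1")


@dataclass
class TimeLog:
    """Per-file and per-rank-initialization timings for one run."""

    n_procs: int
    per_file: list[tuple[str, int, str, float]] = field(default_factory=list)
    # (file_id, rank, plugin, seconds)
    per_rank_init: list[tuple[int, str, float]] = field(default_factory=list)
    # (rank, plugin, seconds)
    failures: list[tuple[str, int, str]] = field(default_factory=list)
    # (file_id, rank, error message)

    def rank_totals(self) -> list[float]:
        totals = [0.0] * self.n_procs
        for rank, _plugin, secs in self.per_rank_init:
            totals[rank] += secs
        for _fid, rank, _plugin, secs in self.per_file:
            totals[rank] += secs
        return totals

    def plugin_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for _fid, _rank, plugin, secs in self.per_file:
            out[plugin] = out.get(plugin, 0.0) + secs
        return out

    def write(self, stream: IO[str]) -> None:
        stream.write(f"# n_procs\t{self.n_procs}\n")
        for rank, plugin, secs in self.per_rank_init:
            stream.write(f"init\t{rank}\t{plugin}\t{secs:.6f}\n")
        for fid, rank, plugin, secs in self.per_file:
            stream.write(f"file\t{fid}\t{rank}\t{plugin}\t{secs:.6f}\n")
        for fid, rank, msg in self.failures:
            stream.write(f"fail\t{fid}\t{rank}\t{msg}\n")

    @classmethod
    def read(cls, stream: IO[str]) -> "TimeLog":
        log = cls(n_procs=1)
        for line in stream:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                if key == "n_procs":
                    log.n_procs = int(value)
                continue
            parts = line.split("\t")
            if parts[0] == "init":
                log.per_rank_init.append((int(parts[1]), parts[2], float(parts[3])))
            elif parts[0] == "file":
                log.per_file.append((parts[1], int(parts[2]), parts[3], float(parts[4])))
            elif parts[0] == "fail":
                log.failures.append((parts[1], int(parts[2]), parts[3]))
            else:
                raise ValueError(f"unknown timelog record {parts[0]!r}")
        return log


# ---------------------------------------------------------------------------
# plugin registry

_REGISTRY: dict[str, tuple[PluginSpec, Callable[[], object]]] = {}


def register_plugin(spec: PluginSpec, factory: Callable[[], object]) -> None:
    """Register an annotator under ``spec.name``.

    ``factory`` builds a fresh annotator instance; each worker calls it once,
    then ``instance.init()`` once, then ``instance.annotate(document)`` per
    document.  Registration order is preserved (stable output ordering).
    """
    if spec.name in _REGISTRY:
        raise ValueError(f"plugin {spec.name!r} already registered")
    _REGISTRY[spec.name] = (spec, factory)


def registered_plugins() -> list[str]:
    return list(_REGISTRY)


def clear_registry() -> None:
    _REGISTRY.clear()


def register_demo_plugins() -> None:
    """Register the bundled mutation/gene/disease taggers (idempotent)."""
    from .plugins import LexiconTagger, MutationTagger

    demos = [
        (PluginSpec(name="mutation", entity_types=("Mutation",)), MutationTagger),
        (
            PluginSpec(name="gene", entity_types=("Gene",), max_procs_per_node=5),
            lambda: LexiconTagger("genes"),
        ),
        (
            PluginSpec(name="disease", entity_types=("Disease",), max_procs_per_node=10),
            lambda: LexiconTagger("diseases"),
        ),
    ]
    for spec, factory in demos:
        if spec.name not in _REGISTRY:
            register_plugin(spec, factory)


# ---------------------------------------------------------------------------
# execution

def _process_rank(
    rank: int,
    file_ids: Sequence[str],
    plugin_names: Sequence[str],
    out_dir: str,
) -> tuple[list, list, list]:
    """Worker body: init each plugin once, annotate every assigned file.

    Returns (per_file, per_rank_init, failures) triples for the TimeLog.
    Runs in the parent for the serial backend and in a forked child for the
    local backend; the registry is inherited either way.
    """
    per_file: list[tuple[str, int, str, float]] = []
    inits: list[tuple[int, str, float]] = []
    failures: list[tuple[str, int, str]] = []

    annotators = {}
    for name in plugin_names:
        spec, factory = _REGISTRY[name]
        t0 = time.monotonic()
        inst = factory()
        inst.init()
        inits.append((rank, name, time.monotonic() - t0))
        annotators[name] = inst

    out = Path(out_dir)
    for fid in file_ids:
        try:
            with open(fid, encoding="utf-8") as fh:
                docs = read_pubtator(fh)
            merged_blocks: list[AnnotatedDocument] = []
            per_plugin_secs = dict.fromkeys(plugin_names, 0.0)
            for adoc in docs:
                per_plugin: list[list] = []
                for name in plugin_names:
                    t0 = time.monotonic()
                    anns = annotators[name].annotate(adoc.document)
                    per_plugin_secs[name] += time.monotonic() - t0
                    per_plugin.append(anns)
                merged_blocks.append(merge_annotations(adoc.document, per_plugin))
            dest = out / Path(fid).name
            with open(dest, "w", encoding="utf-8") as fh:
                write_pubtator(merged_blocks, fh)
            for name in plugin_names:
                per_file.append((fid, rank, name, per_plugin_secs[name]))
        except Exception as exc:  # isolate per-file failures
            failures.append((fid, rank, f"{type(exc).__name__}: {exc}"))
            traceback.print_exc()
    return per_file, inits, failures


def _check_caps(plugin_names: Sequence[str], n_procs: int) -> None:
    for name in plugin_names:
        spec, _ = _REGISTRY[name]
        if n_procs > spec.max_procs_per_node:
            warnings.warn(
                f"plugin {name!r} caps concurrency at "
                f"{spec.max_procs_per_node} processes per node but n_procs="
                f"{n_procs}; ensure the launcher spreads ranks across nodes",
                stacklevel=3,
            )


def run(
    corpus_paths: Sequence[str],
    plugins: Sequence[str],
    out_dir: str,
    strategy: str = "short_board",
    n_procs: int = 1,
    backend: str = "serial",
    model: WorkloadModel | None = None,
    shuffle_seed: int | None = None,
    strict: bool = False,
) -> TimeLog:
    """Annotate a corpus of PubTator files and write one output per input.

    Rank 0 measures the corpus, computes the Assignment under ``strategy``
    with per-file costs predicted by ``model`` (raw character counts by
    default), and dispatches; each worker initializes every plugin exactly
    once and processes exactly its assigned files.  Failed files are logged
    and skipped; with ``strict`` a failure raises after the run completes.
    """
    for name in plugins:
        if name not in _REGISTRY:
            raise KeyError(f"plugin {name!r} is not registered")
    if not plugins:
        raise ValueError("at least one plugin is required")
    _check_caps(plugins, n_procs)

    corpus = measure_corpus(corpus_paths, strict=False)
    costs = (
        {f.file_id: model.predict(f.size_chars) for f in corpus}
        if model is not None
        else None
    )
    assignment = assign(
        corpus, strategy, n_procs, costs=costs, shuffle_seed=shuffle_seed
    )
    Path(out_dir).mkdir(parents=True, exist_ok=True)

    log = TimeLog(n_procs=n_procs)
    if backend == "serial":
        results = [
            _process_rank(rank, group, plugins, out_dir)
            for rank, group in enumerate(assignment.groups)
        ]
    elif backend == "local":
        # fork so children inherit the registry (annotator factories need
        # not be picklable); one process per rank, static assignment
        ctx = mp.get_context("fork")
        with ctx.Pool(processes=n_procs) as pool:
            results = pool.starmap(
                _process_rank,
                [
                    (rank, group, tuple(plugins), out_dir)
                    for rank, group in enumerate(assignment.groups)
                ],
            )
    elif backend == "mpi":
        results = _run_mpi(assignment, plugins, out_dir)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    for per_file, inits, failures in results:
        log.per_file.extend(per_file)
        log.per_rank_init.extend(inits)
        log.failures.extend(failures)
    if strict and log.failures:
        raise RuntimeError(
            f"{len(log.failures)} file(s) failed: "
            + ", ".join(f for f, _, _ in log.failures)
        )
    return log


def _run_mpi(
    assignment: Assignment, plugins: Sequence[str], out_dir: str
) -> list[tuple[list, list, list]]:
    """Scatter the assignment over MPI ranks, gather TimeLogs on rank 0."""
    try:
        from mpi4py import MPI
    except ImportError as exc:  # pragma: no cover - mpi4py optional
        raise RuntimeError(
            "the 'mpi' backend requires mpi4py (install the [mpi] extra) and "
            "an MPI launcher providing at least n_procs ranks"
        ) from exc
    comm = MPI.COMM_WORLD  # pragma: no cover
    if comm.Get_size() < assignment.n_procs:  # pragma: no cover
        raise RuntimeError(
            f"launcher provides {comm.Get_size()} ranks < n_procs={assignment.n_procs}"
        )
    rank = comm.Get_rank()  # pragma: no cover
    group = comm.scatter(  # pragma: no cover
        list(assignment.groups) + [()] * (comm.Get_size() - assignment.n_procs),
        root=0,
    )
    local = _process_rank(rank, group, plugins, out_dir)  # pragma: no cover
    gathered = comm.gather(local, root=0)  # pragma: no cover
    return gathered if rank == 0 else []  # pragma: no cover


@dataclass(frozen=True)
class RunReport:
    """Consolidated metrics for one run: balance plus per-plugin totals."""

    metrics: RunMetrics
    rank_totals: tuple[float, ...]
    plugin_totals: Mapping[str, float]
    n_failures: int

    def write(self, stream: IO[str]) -> None:
        stream.write("# per-rank totals (seconds)\n")
        for rank, secs in enumerate(self.rank_totals):
            stream.write(f"rank\t{rank}\t{secs:.6f}\n")
        stream.write("# per-plugin totals (seconds)\n")
        for plugin, secs in self.plugin_totals.items():
            stream.write(f"plugin\t{plugin}\t{secs:.6f}\n")
        stream.write(f"MET\t{self.metrics.max_seconds:.6f}\n")
        stream.write(f"AET\t{self.metrics.mean_seconds:.6f}\n")
        stream.write(f"LBE\t{self.metrics.lbe:.2f}\n")
        stream.write(f"failures\t{self.n_failures}\n")


def evaluate(timelog: TimeLog) -> RunReport:
    """Balance metrics from a TimeLog: per-rank totals include init time."""
    if not timelog.per_file and not timelog.per_rank_init:
        raise ValueError("empty timelog")
    totals = timelog.rank_totals()
    return RunReport(
        metrics=lbe(totals),
        rank_totals=tuple(totals),
        plugin_totals=timelog.plugin_totals(),
        n_failures=len(timelog.failures),
    )
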