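"""Static load-balancing strategies, balance metrics, and an exact oracle.

Three strategies partition a corpus across worker ranks before any work
starts:

- **modulo** — file at list position P goes to rank ``P % n_procs``; with a
  shuffle seed this simulates random distribution.  Ignores file sizes.
- **round_robin** — sort by cost descending, then deal in serpentine
  (snakelike) passes: ranks 0..n-1, then n-1..0, and so on.  Every rank gets
  (almost) the same *number* of files, with sizes roughly interleaved.
- **short_board** — the greedy longest-processing-time (LPT) heuristic:
  iterate files in cost-descending order and dispatch each to the rank whose
  cumulative load is currently smallest.  Named after the shortest stave of
  a barrel: the least-loaded worker bounds how much more can be poured in.

Balance is measured by the load balancing efficiency LBE = AET / MET, the
average over the maximum per-rank execution time; 1 means perfectly even.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np

from .corpus import Corpus

__all__ = [
    "Assignment",
    "RunMetrics",
    "assign_modulo",
    "assign_round_robin",
    "assign_short_board",
    "assign",
    "makespan",
    "lbe",
    "optimal_makespan",
    "STRATEGIES",
]

#: Default instance caps for the exhaustive optimal-makespan oracle.
ORACLE_MAX_FILES = 14
ORACLE_MAX_PROCS = 4


@dataclass(frozen=True)
class Assignment:
    """A partition of corpus files across ranks; group index = rank."""

    n_procs: int
    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if self.n_procs < 1:
            raise ValueError(f"n_procs must be >= 1, got {self.n_procs}")
        if len(self.groups) != self.n_procs:
            raise ValueError(
                f"{len(self.groups)} groups for n_procs={self.n_procs}"
            )
        flat = [f for g in self.groups for f in g]
        if len(flat) != len(set(flat)):
            raise ValueError("a file appears in more than one group")

    def all_files(self) -> set[str]:
        return {f for g in self.groups for f in g}

    def rank_of(self, file_id: str) -> int:
        for rank, group in enumerate(self.groups):
            if file_id in group:
                return rank
        raise KeyError(file_id)

    def loads(self, costs: Mapping[str, float]) -> list[float]:
        """Cumulative cost per rank."""
        return [sum(costs[f] for f in g) for g in self.groups]

    def to_plan(self, stream: IO[str], costs: Mapping[str, float]) -> None:
        """Serialize as 'rank<TAB>file_id<TAB>cost' lines."""
        for rank, group in enumerate(self.groups):
            for f in group:
                stream.write(f"{rank}\t{f}\t{costs[f]:g}\n")

    @classmethod
    def from_plan(cls, stream: IO[str]) -> tuple["Assignment", dict[str, float]]:
        rows: list[tuple[int, str, float]] = []
        for line in stream:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rank_s, file_id, cost_s = line.split("\t")
            rows.append((int(rank_s), file_id, float(cost_s)))
        if not rows:
            raise ValueError("empty plan file")
        n_procs = max(r for r, _, _ in rows) + 1
        groups: list[list[str]] = [[] for _ in range(n_procs)]
        costs: dict[str, float] = {}
        for rank, file_id, cost in rows:
            groups[rank].append(file_id)
            costs[file_id] = cost
        return cls(n_procs=n_procs, groups=tuple(map(tuple, groups))), costs


@dataclass(frozen=True)
class RunMetrics:
    """Per-rank execution times and the derived balance statistics.

    MET is the maximum per-rank time (the makespan — the run finishes when
    the slowest rank does); AET the arithmetic mean; LBE their ratio.
    """

    per_proc_seconds: tuple[float, ...]
    max_seconds: float = field(init=False)
    mean_seconds: float = field(init=False)
    lbe: float = field(init=False)

    def __post_init__(self) -> None:
        times = self.per_proc_seconds
        if not times:
            raise ValueError("per_proc_seconds must be non-empty")
        if any(t < 0 for t in times):
            raise ValueError("per-process times must be >= 0")
        met = max(times)
        if met == 0:
            raise ValueError("max execution time is 0: no work executed")
        # the mean is mathematically <= the max; clamp 1-ulp float excess so
        # perfectly balanced runs report LBE exactly 1
        aet = min(math.fsum(times) / len(times), met)
        object.__setattr__(self, "max_seconds", float(met))
        object.__setattr__(self, "mean_seconds", float(aet))
        object.__setattr__(self, "lbe", float(aet / met))


def lbe(per_proc_seconds: Sequence[float]) -> RunMetrics:
    """Load balancing efficiency LBE = AET / MET from per-rank times.

    AET is the mean, MET the maximum; LBE lies in (0, 1] and equals 1
    exactly when every rank took the same time.  Raises when no rank did
    any work (MET = 0).
    """
    return RunMetrics(per_proc_seconds=tuple(float(t) for t in per_proc_seconds))


def _resolve_costs(
    corpus: Corpus, costs: Mapping[str, float] | None
) -> dict[str, float]:
    """Default per-file cost is raw size; explicit maps must cover the corpus."""
    if costs is None:
        return {f.file_id: float(f.size_chars) for f in corpus}
    out = {}
    for f in corpus:
        if f.file_id not in costs:
            raise KeyError(f"no cost for file {f.file_id!r}")
        c = float(costs[f.file_id])
        if c < 0:
            raise ValueError(f"negative cost {c} for file {f.file_id!r}")
        out[f.file_id] = c
    return out


def _sorted_by_cost_desc(corpus: Corpus, costs: Mapping[str, float]) -> list[str]:
    # ties on cost break by file_id ascending so assignments are reproducible
    return sorted(
        (f.file_id for f in corpus), key=lambda fid: (-costs[fid], fid)
    )


def assign_modulo(
    corpus: Corpus, n_procs: int, shuffle_seed: int | None = None
) -> Assignment:
    """Position-modulo distribution: file P goes to rank P mod n_procs.

    With ``shuffle_seed`` the file list is first shuffled reproducibly,
    simulating random distribution over arbitrarily ordered input.
    """
    if n_procs < 1:
        raise ValueError(f"n_procs must be >= 1, got {n_procs}")
    order = [f.file_id for f in corpus]
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        order = [order[i] for i in rng.permutation(len(order))]
    groups: list[list[str]] = [[] for _ in range(n_procs)]
    for pos, fid in enumerate(order):
        groups[pos % n_procs].append(fid)
    return Assignment(n_procs=n_procs, groups=tuple(map(tuple, groups)))


def assign_round_robin(
    corpus: Corpus, n_procs: int, costs: Mapping[str, float] | None = None
) -> Assignment:
    """Serpentine dealing of files sorted by cost descending.

    Pass k hands the next ``n_procs`` files to ranks 0..n-1 when k is even
    and n-1..0 when k is odd; the final pass stops when files run out.
    """
    if n_procs < 1:
        raise ValueError(f"n_procs must be >= 1, got {n_procs}")
    cost_map = _resolve_costs(corpus, costs)
    order = _sorted_by_cost_desc(corpus, cost_map)
    groups: list[list[str]] = [[] for _ in range(n_procs)]
    for i, fid in enumerate(order):
        k, j = divmod(i, n_procs)
        rank = j if k % 2 == 0 else n_procs - 1 - j
        groups[rank].append(fid)
    return Assignment(n_procs=n_procs, groups=tuple(map(tuple, groups)))


def assign_short_board(
    corpus: Corpus, n_procs: int, costs: Mapping[str, float] | None = None
) -> Assignment:
    """Greedy LPT: each file, largest first, goes to the least-loaded rank.

    "Load" is cumulative predicted cost, not file count.  Ties on load break
    toward the lowest rank; ties on cost break by file_id ascending.
    """
    if n_procs < 1:
        raise ValueError(f"n_procs must be >= 1, got {n_procs}")
    cost_map = _resolve_costs(corpus, costs)
    order = _sorted_by_cost_desc(corpus, cost_map)
    groups: list[list[str]] = [[] for _ in range(n_procs)]
    loads = [0.0] * n_procs
    for fid in order:
        rank = min(range(n_procs), key=lambda r: (loads[r], r))
        groups[rank].append(fid)
        loads[rank] += cost_map[fid]
    return Assignment(n_procs=n_procs, groups=tuple(map(tuple, groups)))


STRATEGIES = {
    "modulo": assign_modulo,
    "round_robin": assign_round_robin,
    "short_board": assign_short_board,
}


def assign(
    corpus: Corpus,
    strategy: str,
    n_procs: int,
    costs: Mapping[str, float] | None = None,
    shuffle_seed: int | None = None,
) -> Assignment:
    """Dispatch to a strategy by name."""
    if strategy == "modulo":
        return assign_modulo(corpus, n_procs, shuffle_seed=shuffle_seed)
    if strategy == "round_robin":
        return assign_round_robin(corpus, n_procs, costs=costs)
    if strategy == "short_board":
        return assign_short_board(corpus, n_procs, costs=costs)
    raise ValueError(
        f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}"
    )


def makespan(assignment: Assignment, costs: Mapping[str, float]) -> float:
    """Maximum over ranks of the summed member costs (0 for an empty corpus)."""
    loads = assignment.loads(costs)
    return max(loads) if loads else 0.0


def optimal_makespan(
    costs: Sequence[float],
    n_procs: int,
    max_files: int = ORACLE_MAX_FILES,
    max_procs: int = ORACLE_MAX_PROCS,
) -> float:
    """Exact minimum makespan by branch-and-bound enumeration.

    Only intended for small instances (testing oracle); symmetric
    assignments are pruned by never opening rank r+1 before rank r has work.
    Raises on instances above the caps — use the simulator for anything
    bigger.
    """
    if n_procs < 1:
        raise ValueError(f"n_procs must be >= 1, got {n_procs}")
    if len(costs) > max_files or n_procs > max_procs:
        raise ValueError(
            f"instance ({len(costs)} files, {n_procs} procs) exceeds the oracle "
            f"cap ({max_files} files, {max_procs} procs); use the simulator for "
            "large instances"
        )
    if any(c < 0 for c in costs):
        raise ValueError("costs must be >= 0")
    items = sorted((float(c) for c in costs), reverse=True)
    if not items:
        return 0.0
    total = sum(items)
    best = total  # everything on one rank is always feasible

    loads = [0.0] * n_procs

    def dfs(i: int, used: int) -> None:
        nonlocal best
        if i == len(items):
            best = min(best, max(loads))
            return
        if max(loads) >= best:
            return
        # perfect lower bound check: even an ideal split of the remainder
        # cannot beat the incumbent
        remaining = total - sum(loads)
        lb = max(max(loads), (sum(loads) + remaining) / n_procs)
        if lb >= best:
            return
        seen: set[float] = set()
        limit = min(used + 1, n_procs)  # symmetry: open at most one new rank
        for r in range(limit):
            if loads[r] in seen:  # identical loads are interchangeable
                continue
            seen.add(loads[r])
            loads[r] += items[i]
            if loads[r] < best:
                dfs(i + 1, max(used, r + 1))
            loads[r] -= items[i]

    dfs(0, 0)
    return best
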