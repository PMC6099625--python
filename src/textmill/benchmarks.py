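"""Bundled benchmark timing fixtures.

Two small tables measured on a production multi-node NER deployment ship
with the package: per-strategy maximum/average execution times across
process counts, and serial total time versus input size.  They anchor the
workload model's units and provide worked examples for the LBE metric.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_strategy_timings", "load_serial_timings"]

#: Strategy labels used in the bundled timing table mapped onto the names of
#: the implementations in :mod:`textmill.scheduling` ("random" is modulo
#: distribution over randomly ordered input).
STRATEGY_ALIASES = {"random": "modulo"}


def _read(name: str) -> str:
    return resources.files("textmill.data").joinpath(name).read_text("utf-8")


def load_strategy_timings() -> pd.DataFrame:
    """Per-strategy MET/AET benchmark: columns n_procs, strategy,
    max_seconds, mean_seconds."""
    from io import StringIO

    return pd.read_csv(
        StringIO(_read("strategy_timings.tsv")),
        sep="\t",
        comment="#",
        names=["n_procs", "strategy", "max_seconds", "mean_seconds"],
    )


def load_serial_timings() -> list[tuple[float, float]]:
    """Serial (size_mb, total_seconds) points for workload-model fitting."""
    points = []
    for line in _read("serial_timings.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        size_s, secs_s = line.split("\t")
        points.append((float(size_s), float(secs_s)))
    return points
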