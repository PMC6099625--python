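"""Corpus representation, workload modelling, and synthetic corpus generation.

The cost of running document-level NER over a file is, to good approximation,
an affine function of the file's size in characters: tools pay a fixed
initialization/overhead cost plus a per-character processing cost.  The
:class:`WorkloadModel` captures that line; schedulers consume predicted
per-file costs (or raw sizes, which order identically under the default
identity model).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pubtator import Document, read_pubtator

__all__ = [
    "CorpusFile",
    "Corpus",
    "WorkloadModel",
    "measure_corpus",
    "fit_time_model",
    "predict_cost",
    "generate_corpus",
    "materialize_corpus",
    "CHARS_PER_MB",
    "IDENTITY_MODEL",
]

# Fixture-level convention for interoperating MB-scale fits with
# character-scale corpora.
CHARS_PER_MB = 1_000_000


@dataclass(frozen=True)
class CorpusFile:
    """A schedulable unit: one file with its measured size in characters."""

    file_id: str
    size_chars: int

    def __post_init__(self) -> None:
        if self.size_chars < 0:
            raise ValueError(f"size_chars must be >= 0, got {self.size_chars}")
        if not self.file_id:
            raise ValueError("file_id must be non-empty")


@dataclass(frozen=True)
class Corpus:
    """An ordered collection of corpus files with unique ids."""

    files: tuple[CorpusFile, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [f.file_id for f in self.files]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate file_ids in corpus: {dupes}")

    def __len__(self) -> int:
        return len(self.files)

    def __iter__(self):
        return iter(self.files)

    @property
    def total_chars(self) -> int:
        return sum(f.size_chars for f in self.files)

    def sizes(self) -> dict[str, int]:
        return {f.file_id: f.size_chars for f in self.files}


@dataclass(frozen=True)
class WorkloadModel:
    """Affine size → seconds model: cost = intercept + slope * size.

    ``size_unit`` records what one unit of size means ("chars" or "MB") so
    MB-scale fits from serial benchmarks can price character-scale corpora
    via an explicit conversion.
    """

    intercept: float = 0.0
    slope: float = 1.0
    size_unit: str = "chars"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if self.intercept < 0:
            raise ValueError(f"intercept must be >= 0, got {self.intercept}")
        if self.size_unit not in ("chars", "MB"):
            raise ValueError(f"unknown size_unit {self.size_unit!r}")

    def predict(self, size_chars: float) -> float:
        size = size_chars / CHARS_PER_MB if self.size_unit == "MB" else size_chars
        return self.intercept + self.slope * size


#: Identity model — per-file cost equals raw character count.
IDENTITY_MODEL = WorkloadModel(intercept=0.0, slope=1.0, size_unit="chars")


def measure_corpus(
    inputs: Iterable[str | os.PathLike | Document],
    strict: bool = True,
) -> Corpus:
    """Build a corpus from documents or PubTator file paths.

    Each entry becomes one :class:`CorpusFile` whose size is the exact
    character count of the composite text (summed over a file's documents
    for multi-document files).  Input order is preserved.

    With ``strict=False`` a file that fails PubTator parsing is sized by its
    raw character count instead of aborting — sizes are only scheduling
    hints, and downstream processing will surface the parse error per file.
    """
    from .pubtator import PubTatorFormatError

    files: list[CorpusFile] = []
    for item in inputs:
        if isinstance(item, Document):
            files.append(CorpusFile(file_id=item.doc_id, size_chars=item.size_chars))
        else:
            path = Path(item)
            try:
                with open(path, encoding="utf-8") as fh:
                    raw = fh.read()
            except OSError as exc:
                raise OSError(f"cannot read corpus file {path}: {exc}") from exc
            try:
                docs = read_pubtator(raw)
                size = sum(d.document.size_chars for d in docs)
            except PubTatorFormatError:
                if strict:
                    raise
                size = len(raw)
            files.append(CorpusFile(file_id=str(path), size_chars=size))
    return Corpus(files=tuple(files))


def fit_time_model(
    points: Sequence[tuple[float, float]], size_unit: str = "chars"
) -> WorkloadModel:
    """Ordinary least-squares line through (size, seconds) observations.

    Requires at least two points with at least two distinct sizes.  The fit
    is unweighted.  A negative fitted intercept is clamped to zero (a
    zero-size file cannot have negative cost).
    """
    if len(points) < 2:
        raise ValueError(f"need >= 2 timing points, got {len(points)}")
    sizes = np.asarray([p[0] for p in points], dtype=float)
    secs = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(sizes).size < 2:
        raise ValueError("degenerate fit: all sizes equal")
    slope, intercept = np.polyfit(sizes, secs, deg=1)
    if slope <= 0:
        raise ValueError(f"fitted slope {slope:.4g} is not positive")
    return WorkloadModel(
        intercept=max(float(intercept), 0.0),
        slope=float(slope),
        size_unit=size_unit,
    )


def predict_cost(model: WorkloadModel, file: CorpusFile) -> float:
    """Predicted processing seconds for one corpus file."""
    return model.predict(file.size_chars)


def generate_corpus(
    n_files: int,
    distribution: str = "lognormal",
    params: dict | None = None,
    seed: int = 0,
    prefix: str = "F",
) -> Corpus:
    """Draw a synthetic corpus with i.i.d. file sizes.

    Distributions and their parameters (all sizes in characters):

    - ``uniform``: ``low`` (default 2_000), ``high`` (default 40_000)
    - ``lognormal``: ``mean`` (default 9.2), ``sigma`` (default 1.0) of the
      underlying normal — median ≈ 10k characters, a typical abstract-to-
      full-text mix
    - ``pareto``: ``alpha`` tail index (default 1.2), ``xm`` scale (default
      1_000) — heavy-tailed corpora where a few files are extremely long
      while many others are short
    - ``two_point``: ``small`` (default 1_000), ``large`` (default 100_000),
      ``p_large`` (default 0.05)

    Sizes are rounded to integers and floored at 1 character.  Reproducible
    for a fixed seed.
    """
    if n_files < 0:
        raise ValueError(f"n_files must be >= 0, got {n_files}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)

    if distribution == "uniform":
        low = params.pop("low", 2_000)
        high = params.pop("high", 40_000)
        if not 0 <= low <= high:
            raise ValueError(f"need 0 <= low <= high, got {low}, {high}")
        sizes = rng.uniform(low, high, size=n_files)
    elif distribution == "lognormal":
        mean = params.pop("mean", 9.2)
        sigma = params.pop("sigma", 1.0)
        if sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {sigma}")
        sizes = rng.lognormal(mean, sigma, size=n_files)
    elif distribution == "pareto":
        alpha = params.pop("alpha", 1.2)
        xm = params.pop("xm", 1_000)
        if alpha <= 0 or xm <= 0:
            raise ValueError(f"need alpha > 0 and xm > 0, got {alpha}, {xm}")
        sizes = xm * (1.0 + rng.pareto(alpha, size=n_files))
    elif distribution == "two_point":
        small = params.pop("small", 1_000)
        large = params.pop("large", 100_000)
        p_large = params.pop("p_large", 0.05)
        if not 0 <= p_large <= 1:
            raise ValueError(f"p_large must be in [0, 1], got {p_large}")
        sizes = np.where(rng.random(n_files) < p_large, large, small).astype(float)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    if params:
        raise ValueError(f"unused params for {distribution}: {sorted(params)}")

    sizes = np.maximum(np.rint(sizes).astype(int), 1)
    width = max(len(str(max(n_files - 1, 0))), 1)
    files = tuple(
        CorpusFile(file_id=f"{prefix}{i:0{width}d}", size_chars=int(s))
        for i, s in enumerate(sizes)
    )
    return Corpus(files=files)


# entity mentions sprinkled into synthetic documents so demonstration NER
# plugins produce non-empty output on generated corpora
_MENTION_POOL = (
    "BRAF", "TP53", "EGFR", "KRAS", "V600E", "T790M", "c.123A>G", "c.35G>T",
    "melanoma", "breast cancer", "leukemia", "lung cancer", "glioblastoma",
)


def materialize_corpus(
    corpus: Corpus,
    out_dir: str | os.PathLike,
    seed: int = 0,
    mention_rate: float = 0.15,
) -> list[Path]:
    """Write one PubTator file per corpus file with the exact listed size.

    Content is random word-like filler with entity mentions (genes,
    diseases, mutations) interspersed at ``mention_rate`` per token, so
    the demonstration taggers find work to do — useful for end-to-end
    pipeline tests, not for NER quality.  The composite text (title + one
    space + body) of each document has exactly ``size_chars`` characters.
    """
    from .pubtator import AnnotatedDocument, write_pubtator

    rng = np.random.default_rng(seed)
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def rand_text(k: int) -> str:
        """Exactly k characters of space-separated tokens (no edge spaces)."""
        if k <= 0:
            return ""
        tokens: list[str] = []
        length = -1  # joining m tokens costs m-1 separators
        while length < k:
            if rng.random() < mention_rate:
                tok = _MENTION_POOL[rng.integers(len(_MENTION_POOL))]
            else:
                tok = "".join(rng.choice(list(letters), size=rng.integers(3, 9)))
            tokens.append(tok)
            length += len(tok) + 1
        text = " ".join(tokens)[:k]
        if text.endswith(" "):  # no trailing separator
            text = text[:-1] + "z"
        return text

    paths = []
    for cf in corpus:
        n = cf.size_chars
        title_len = min(max(n // 10, 1), 200, n)
        if n - title_len - 1 >= 1:
            body_len = n - title_len - 1
        else:  # too small to split: the title alone carries the full size
            title_len, body_len = n, 0

        doc = Document(
            doc_id=cf.file_id,
            title=rand_text(title_len),
            body=rand_text(body_len),
        )
        path = out / f"{cf.file_id}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            write_pubtator([AnnotatedDocument(document=doc)], fh)
        paths.append(path)
    return paths
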