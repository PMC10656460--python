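"""Anchors, chaining tasks, synthetic task generation, and anchor TSV I/O.

An anchor is a single exact seed match between a query and a reference,
stored by its 0-based *inclusive end* positions on both sequences plus the
span of the match.  A :class:`ChainTask` bundles the sorted anchor set of
one read/strand; it is both the unit of chaining and the unit of
scheduling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np

__all__ = [
    "Anchor",
    "ChainTask",
    "GeneratorConfig",
    "AnchorTableError",
    "generate_tasks",
    "write_anchor_table",
    "read_anchor_table",
]

TABLE_HEADER = "task_id\tx\ty\tw\tstrand"


@dataclass(frozen=True, order=True)
class Anchor:
    """One seed match.

    Attributes
    ----------
    x : int
        Reference end position of the match (0-based, inclusive).
    y : int
        Query end position of the match (0-based, inclusive).
    w : int
        Span of the match in bases.
    """

    x: int
    y: int
    w: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"anchor positions must be >= 0, got ({self.x}, {self.y})")
        if self.w < 1:
            raise ValueError(f"anchor span must be >= 1, got w={self.w}")
        if self.w > self.x + 1 or self.w > self.y + 1:
            raise ValueError(
                f"span w={self.w} does not fit before end positions ({self.x}, {self.y})"
            )


@dataclass(frozen=True)
class ChainTask:
    """A sorted anchor set for one read/strand."""

    task_id: str
    anchors: tuple[Anchor, ...]
    query_length: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchors", tuple(self.anchors))
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev = None
        for a in self.anchors:
            key = (a.x, a.y)
            if prev is not None and key <= prev:
                raise ValueError(
                    f"anchors of task {self.task_id!r} must be strictly "
                    f"increasing by (x, y); {key} follows {prev}"
                )
            prev = key

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def n(self) -> int:
        return len(self.anchors)

    def coord_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (x, y, w) as int64 arrays."""
        if not self.anchors:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        arr = np.array([(a.x, a.y, a.w) for a in self.anchors], dtype=np.int64)
        return arr[:, 0], arr[:, 1], arr[:, 2]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the planted-chain task generator.

    ``anchors_per_task`` may be a single count or an inclusive
    ``(low, high)`` range sampled uniformly per task.
    """

    n_tasks: int
    anchors_per_task: Union[int, tuple[int, int]] = 100
    planted_chains_per_task: int = 1
    noise_fraction: float = 0.25
    span_k: int = 15
    coord_range: int = 100_000
    step_jitter: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tasks < 0:
            raise ValueError(f"n_tasks must be >= 0, got {self.n_tasks}")
        apt = self.anchors_per_task
        if isinstance(apt, int):
            if apt < 0:
                raise ValueError(f"anchors_per_task must be >= 0, got {apt}")
        else:
            apt = tuple(int(v) for v in apt)
            object.__setattr__(self, "anchors_per_task", apt)
            if len(apt) != 2 or apt[0] < 0 or apt[1] < apt[0]:
                raise ValueError(f"anchors_per_task range invalid: {apt}")
        if self.planted_chains_per_task < 0:
            raise ValueError(
                f"planted_chains_per_task must be >= 0, got {self.planted_chains_per_task}"
            )
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError(f"noise_fraction must be in [0, 1], got {self.noise_fraction}")
        if self.span_k < 1:
            raise ValueError(f"span_k must be >= 1, got {self.span_k}")
        if self.coord_range < 1:
            raise ValueError(f"coord_range must be >= 1, got {self.coord_range}")
        if self.step_jitter < 0:
            raise ValueError(f"step_jitter must be >= 0, got {self.step_jitter}")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown generator config fields: {sorted(unknown)}")
        if isinstance(data.get("anchors_per_task"), list):
            data["anchors_per_task"] = tuple(data["anchors_per_task"])
        return cls(**data)


def _task_size(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    apt = cfg.anchors_per_task
    if isinstance(apt, int):
        return apt
    return int(rng.integers(apt[0], apt[1] + 1))


def _plant_chain(
    cfg: GeneratorConfig, rng: np.random.Generator, length: int, taken: set[tuple[int, int]]
) -> list[Anchor]:
    """Plant one colinear chain: consecutive anchors advance on both axes
    by span_k +/- step_jitter (each axis jittered independently, step >= 1)."""
    k, j = cfg.span_k, cfg.step_jitter
    # leave head room so the chain start satisfies w <= pos+1
    lo = k - 1
    hi = max(lo, cfg.coord_range - length * (k + j))
    x = int(rng.integers(lo, hi + 1))
    y = int(rng.integers(lo, hi + 1))
    out: list[Anchor] = []
    for step in range(length):
        if step > 0:
            x += max(1, k + int(rng.integers(-j, j + 1)))
            y += max(1, k + int(rng.integers(-j, j + 1)))
        if (x, y) in taken:
            continue
        taken.add((x, y))
        out.append(Anchor(x, y, k))
    return out


def generate_tasks(cfg: GeneratorConfig) -> list[ChainTask]:
    """Generate ``cfg.n_tasks`` synthetic chaining tasks.

    Each task holds ``planted_chains_per_task`` colinear chains plus
    uniformly scattered noise anchors (``noise_fraction`` of the task);
    anchors are sorted by (x, y) and strictly deduplicated.  Fully
    deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    tasks: list[ChainTask] = []
    for t in range(cfg.n_tasks):
        n_total = _task_size(cfg, rng)
        n_noise = int(round(cfg.noise_fraction * n_total))
        n_planted = n_total - n_noise
        taken: set[tuple[int, int]] = set()
        anchors: list[Anchor] = []
        if cfg.planted_chains_per_task > 0 and n_planted > 0:
            per = n_planted // cfg.planted_chains_per_task
            sizes = [per] * cfg.planted_chains_per_task
            for i in range(n_planted - per * cfg.planted_chains_per_task):
                sizes[i] += 1
            for size in sizes:
                if size:
                    anchors.extend(_plant_chain(cfg, rng, size, taken))
        lo = cfg.span_k - 1  # noise anchors must also satisfy w <= pos+1
        hi = max(lo, cfg.coord_range)
        while len(anchors) < n_total:
            x = int(rng.integers(lo, hi + 1))
            y = int(rng.integers(lo, hi + 1))
            if (x, y) in taken:
                continue  # redraw on collision to keep (x, y) unique
            taken.add((x, y))
            anchors.append(Anchor(x, y, cfg.span_k))
        anchors.sort(key=lambda a: (a.x, a.y))
        tasks.append(ChainTask(task_id=f"task{t:05d}", anchors=tuple(anchors)))
    return tasks


class AnchorTableError(ValueError):
    """Raised when an anchor TSV file is malformed."""


def write_anchor_table(tasks: Iterable[ChainTask], destination: Union[str, Path, IO[str]]) -> None:
    """Write tasks as TSV: header ``task_id  x  y  w  strand``, one anchor per row."""

    def _emit(fh: IO[str]) -> None:
        fh.write(TABLE_HEADER + "\n")
        for task in tasks:
            for a in task.anchors:
                fh.write(f"{task.task_id}\t{a.x}\t{a.y}\t{a.w}\t{task.strand}\n")

    if hasattr(destination, "write"):
        _emit(destination)  # type: ignore[arg-type]
    else:
        with open(destination, "w") as fh:
            _emit(fh)


def read_anchor_table(source: Union[str, Path, IO[str]]) -> list[ChainTask]:
    """Parse the anchor TSV dialect.

    Rows are grouped by task_id preserving first-appearance order; anchors
    within each task are sorted by (x, y).  Malformed rows raise
    :class:`AnchorTableError` with the offending line number.
    """

    def _parse(fh: IO[str]) -> list[ChainTask]:
        header = fh.readline().rstrip("\n")
        if header and header != TABLE_HEADER:
            raise AnchorTableError(
                f"line 1: expected header {TABLE_HEADER!r}, got {header!r}"
            )
        groups: dict[str, list[Anchor]] = {}
        strands: dict[str, str] = {}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise AnchorTableError(
                    f"line {lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            task_id, xs, ys, ws, strand = parts
            try:
                x, y, w = int(xs), int(ys), int(ws)
            except ValueError:
                raise AnchorTableError(
                    f"line {lineno}: non-integer coordinate field in {parts[1:4]}"
                ) from None
            if strand not in ("+", "-"):
                raise AnchorTableError(f"line {lineno}: invalid strand {strand!r}")
            try:
                anchor = Anchor(x, y, w)
            except ValueError as exc:
                raise AnchorTableError(f"line {lineno}: {exc}") from None
            prev_strand = strands.setdefault(task_id, strand)
            if prev_strand != strand:
                raise AnchorTableError(
                    f"line {lineno}: strand {strand!r} conflicts with earlier "
                    f"{prev_strand!r} for task {task_id!r}"
                )
            groups.setdefault(task_id, []).append(anchor)
        tasks = []
        for task_id, anchors in groups.items():
            anchors.sort(key=lambda a: (a.x, a.y))
            tasks.append(
                ChainTask(task_id=task_id, anchors=tuple(anchors), strand=strands[task_id])
            )
        return tasks

    if hasattr(source, "read"):
        return _parse(source)  # type: ignore[arg-type]
    with open(source) as fh:
        return _parse(fh)
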