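"""Discrete-event simulation of prediction-based hardware/software task
placement.

``Y`` software threads each work through a round-robin share of the
chaining tasks.  On reaching a chaining item a thread predicts the task's
hardware and software times; if the software prediction is lower or equal
the task runs in place, otherwise the thread looks for a hardware kernel
whose queue wait plus hardware time beats the software prediction, queues
the task there (per-kernel FIFO), and blocks until the kernel completes
it.  True service times come from a truth model (exact, or multiplicative
noise on the predictions).
"""

from __future__ import annotations

import dataclasses
import heapq
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .anchors import ChainTask
from .chaining import UNBOUNDED, ChainingParams, chain_scores
from .perfmodel import (
    HwFeatures,
    PerfCoeffs,
    SwFeatures,
    hw_features,
    predict_hw,
    predict_sw,
)

__all__ = [
    "KernelState",
    "SimConfig",
    "Placement",
    "TaskRecord",
    "KernelEvent",
    "SimResult",
    "kernel_wait",
    "decide_placement",
    "simulate",
]

SOFTWARE = "SOFTWARE"
HARDWARE = "HARDWARE"


@dataclass
class _QueueEntry:
    task_id: str
    predicted_ms: float
    start: float  # true start time on the kernel
    completion: float  # true completion time


@dataclass
class KernelState:
    """One hardware kernel: the task it is running and its FIFO access queue."""

    kernel_index: int
    _entries: list[_QueueEntry] = field(default_factory=list)
    _free_at: float = 0.0
    busy_ms: float = 0.0
    log: list["KernelEvent"] = field(default_factory=list)

    def _prune(self, now: float) -> None:
        self._entries = [e for e in self._entries if e.completion > now]

    def busy_until(self, now: float) -> float:
        """Completion time of the task running at ``now`` (== ``now`` if idle)."""
        for e in self._entries:
            if e.start <= now < e.completion:
                return e.completion
        return now

    def queued_predictions(self, now: float) -> list[float]:
        """Predicted durations of queued (not yet started) tasks, FIFO order."""
        return [e.predicted_ms for e in self._entries if e.start > now]

    def enqueue(self, task_id: str, predicted_ms: float, true_ms: float, now: float) -> float:
        """Append a task to the FIFO; returns its true completion time."""
        self._prune(now)
        start = max(self._free_at, now)
        completion = start + true_ms
        self._entries.append(_QueueEntry(task_id, predicted_ms, start, completion))
        self._free_at = completion
        self.busy_ms += true_ms
        self.log.append(KernelEvent(task_id=task_id, start=start, completion=completion))
        return completion


@dataclass(frozen=True)
class KernelEvent:
    task_id: str
    start: float
    completion: float


def kernel_wait(state: KernelState, now: float) -> float:
    """Predicted delay before the kernel could start a task offered at ``now``:
    remaining service of the running task plus the predicted durations of
    everything already queued."""
    remaining = max(0.0, state.busy_until(now) - now)
    return remaining + sum(state.queued_predictions(now))


@dataclass(frozen=True)
class Placement:
    """Where one task ran and the predictions that drove the decision."""

    kind: str  # SOFTWARE or HARDWARE
    kernel_index: int = -1
    t_hw_pred: float = 0.0
    t_sw_pred: float = 0.0
    t_wait_pred: float = 0.0


def decide_placement(
    t_hw: float, t_sw: float, kernels: Sequence[KernelState], now: float
) -> Placement:
    """The placement policy.

    Software wins outright when ``t_sw <= t_hw``.  Otherwise, among
    kernels whose ``wait + t_hw`` still beats ``t_sw``, the one with the
    minimal wait is chosen (ties to the lowest index); if none qualifies
    the task stays in software.
    """
    if t_sw <= t_hw or not kernels:
        return Placement(kind=SOFTWARE, t_hw_pred=t_hw, t_sw_pred=t_sw)
    best_wait = None
    best_kernel = None
    for state in kernels:
        wait = kernel_wait(state, now)
        if wait + t_hw < t_sw and (best_wait is None or wait < best_wait):
            best_wait = wait
            best_kernel = state.kernel_index
    if best_kernel is None:
        return Placement(kind=SOFTWARE, t_hw_pred=t_hw, t_sw_pred=t_sw)
    return Placement(
        kind=HARDWARE,
        kernel_index=best_kernel,
        t_hw_pred=t_hw,
        t_sw_pred=t_sw,
        t_wait_pred=best_wait,
    )


@dataclass(frozen=True)
class TaskRecord:
    """Precomputed per-task features, the scheduler's working currency."""

    task_id: str
    hw: HwFeatures
    sw: SwFeatures


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration.

    ``truth_model`` is ``"exact"`` (true time = predicted time) or
    ``"noisy"`` (true time = prediction times a positive factor drawn as
    ``1 + truth_sigma * N(0, 1)``, floored at 0.01, seeded).
    ``per_task_overhead`` is the (pre, post) non-chaining work per task in
    ms, standing in for seeding/alignment/output stages.
    """

    Y: int = 8
    N: int = 1
    coeffs: PerfCoeffs = field(default_factory=PerfCoeffs)
    truth_model: str = "exact"
    truth_sigma: float = 0.1
    per_task_overhead: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Y < 1:
            raise ValueError(f"Y must be >= 1, got {self.Y}")
        if self.N < 0:
            raise ValueError(f"N must be >= 0, got {self.N}")
        if self.truth_model not in ("exact", "noisy"):
            raise ValueError(f"truth_model must be 'exact' or 'noisy', got {self.truth_model!r}")
        if self.truth_sigma < 0:
            raise ValueError("truth_sigma must be >= 0")
        pre, post = self.per_task_overhead
        if pre < 0 or post < 0:
            raise ValueError("per_task_overhead must be >= 0")


@dataclass
class SimResult:
    makespan: float
    placements: list[Placement]
    task_ids: list[str]
    true_elapsed: list[float]  # chaining wait+service per task (excl. pre/post)
    kernel_busy_ms: list[float]
    kernel_utilization: list[float]
    kernel_logs: list[list[KernelEvent]]
    n_hardware: int
    n_software: int


def _task_records(
    tasks: Sequence[Union[ChainTask, TaskRecord]], params: ChainingParams
) -> list[TaskRecord]:
    records = []
    for task in tasks:
        if isinstance(task, TaskRecord):
            records.append(task)
            continue
        # software runs the exact (unbounded) loop; hardware the fixed-H pipeline
        dp = chain_scores(task, dataclasses.replace(params, H=UNBOUNDED))
        records.append(
            TaskRecord(
                task_id=task.task_id,
                hw=hw_features(task, params.H, params.P),
                sw=SwFeatures(sum_trip_count=int(dp.trip_count.sum())),
            )
        )
    return records


def simulate(
    tasks: Sequence[Union[ChainTask, TaskRecord]],
    cfg: SimConfig,
    params: ChainingParams | None = None,
) -> SimResult:
    """Run the placement simulation over a workload.

    Tasks are dealt round-robin to ``cfg.Y`` thread work lists.  Each
    thread processes its items in order: pre-work, then the chaining
    decision (software in place, or blocking offload to the chosen
    kernel's FIFO), then post-work.  Simultaneous decisions are ordered by
    (time, thread index, sequence number).  Makespan is the latest thread
    finish time.  Deterministic for a fixed config/seed/workload.
    """
    params = params or ChainingParams()
    records = _task_records(tasks, params)
    n_tasks = len(records)
    rng = np.random.default_rng(cfg.seed)
    if cfg.truth_model == "noisy":
        factors = np.maximum(
            0.01, 1.0 + cfg.truth_sigma * rng.standard_normal((n_tasks, 2))
        )
    else:
        factors = np.ones((n_tasks, 2))

    kernels = [KernelState(kernel_index=i) for i in range(cfg.N)]
    pre_ms, post_ms = cfg.per_task_overhead

    # thread work lists, round-robin by task order
    work: list[list[int]] = [[] for _ in range(cfg.Y)]
    for idx in range(n_tasks):
        work[idx % cfg.Y].append(idx)

    placements: list[Placement | None] = [None] * n_tasks
    elapsed: list[float] = [0.0] * n_tasks
    thread_finish = [0.0] * cfg.Y

    # events: (decision time, thread index, sequence) -> thread ready to
    # decide placement of its next item (pre-work already accounted)
    heap: list[tuple[float, int, int]] = []
    seq = 0
    cursor = [0] * cfg.Y
    for t in range(cfg.Y):
        if work[t]:
            heapq.heappush(heap, (pre_ms, t, seq))
            seq += 1
    while heap:
        now, t, _ = heapq.heappop(heap)
        idx = work[t][cursor[t]]
        rec = records[idx]
        t_hw = predict_hw(rec.hw, cfg.coeffs)
        t_sw = predict_sw(rec.sw, cfg.coeffs)
        placement = decide_placement(t_hw, t_sw, kernels, now)
        if placement.kind == SOFTWARE:
            true_time = t_sw * float(factors[idx, 1])
            done = now + true_time
        else:
            true_time = t_hw * float(factors[idx, 0])
            done = kernels[placement.kernel_index].enqueue(
                rec.task_id, t_hw, true_time, now
            )
        placements[idx] = placement
        elapsed[idx] = done - now
        finish = done + post_ms
        cursor[t] += 1
        if cursor[t] < len(work[t]):
            heapq.heappush(heap, (finish + pre_ms, t, seq))
            seq += 1
        else:
            thread_finish[t] = finish

    makespan = max(thread_finish) if n_tasks else 0.0
    busy = [k.busy_ms for k in kernels]
    util = [b / makespan if makespan > 0 else 0.0 for b in busy]
    final = [p for p in placements if p is not None]
    return SimResult(
        makespan=makespan,
        placements=final,
        task_ids=[r.task_id for r in records],
        true_elapsed=elapsed,
        kernel_busy_ms=busy,
        kernel_utilization=util,
        kernel_logs=[list(k.log) for k in kernels],
        n_hardware=sum(1 for p in final if p.kind == HARDWARE),
        n_software=sum(1 for p in final if p.kind == SOFTWARE),
    )
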