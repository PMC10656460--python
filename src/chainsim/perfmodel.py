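"""Linear runtime predictors for chaining tasks on hardware and software.

Hardware time for a task of ``n`` anchors is modelled as a per-task data
transfer term plus a pipelined execution term plus a fixed overhead::

    T_hw = K1 * n + E * total_subparts + C1,      E = II * T_clock

where ``total_subparts`` counts the fixed-bound inner-loop sub-partitions
the pipeline issues.  Software time is linear in the total number of
inner-loop iterations::

    T_sw = K2 * sum_trip_count + C2

Both predictions clamp at zero.  ``E`` is the only identifiable quantity
from timing data, so fitting estimates it directly; ``II`` and ``T_clock``
are configuration metadata.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Literal, Sequence, Union

import numpy as np

from .anchors import ChainTask
from .chaining import ChainingParams, DPResult, chain_scores

__all__ = [
    "PerfCoeffs",
    "HwFeatures",
    "SwFeatures",
    "TimingSample",
    "FitError",
    "hw_features",
    "sw_features",
    "predict_hw",
    "predict_sw",
    "fit_coeffs",
    "synthesize_timings",
    "measure_software_times",
    "write_timing_table",
    "read_timing_table",
    "write_coeffs",
    "read_coeffs",
]

DEFAULT_II = 2.0

TIMING_HEADER = "task_id\tn\ttotal_subparts\tsum_trip_count\tobserved_hw_ms\tobserved_sw_ms"


@dataclass(frozen=True)
class PerfCoeffs:
    """Predictor constants (all times in ms).

    ``K1``: ms per anchor transferred; ``C1``: fixed hardware overhead;
    ``II``: pipeline initiation interval (cycles per sub-partition);
    ``T_clock``: clock period (ms per cycle); ``K2``: ms per software
    inner-loop iteration; ``C2``: fixed software overhead.
    """

    K1: float = 0.0
    C1: float = 0.0
    II: float = DEFAULT_II
    T_clock: float = 0.0
    K2: float = 0.0
    C2: float = 0.0
    residual_rms_hw: float | None = None
    residual_rms_sw: float | None = None

    def __post_init__(self) -> None:
        if self.II < 0 or self.T_clock < 0:
            raise ValueError("II and T_clock must be >= 0")

    @property
    def E(self) -> float:
        """Combined ms-per-sub-partition execution coefficient, II * T_clock."""
        return self.II * self.T_clock

    @classmethod
    def from_E(cls, K1: float, E: float, C1: float, II: float = DEFAULT_II, **kw) -> "PerfCoeffs":
        return cls(K1=K1, C1=C1, II=II, T_clock=E / II, **kw)


@dataclass(frozen=True)
class HwFeatures:
    n: int
    total_subparts: int

    def __post_init__(self) -> None:
        if self.n < 0 or self.total_subparts < 0:
            raise ValueError("hardware features must be >= 0")


@dataclass(frozen=True)
class SwFeatures:
    sum_trip_count: int

    def __post_init__(self) -> None:
        if self.sum_trip_count < 0:
            raise ValueError("sum_trip_count must be >= 0")


@dataclass(frozen=True)
class TimingSample:
    """One measured (or synthesized) task timing with its features."""

    n: int
    total_subparts: int
    sum_trip_count: int
    observed_hw_ms: float | None = None
    observed_sw_ms: float | None = None
    task_id: str = ""

    def __post_init__(self) -> None:
        if self.observed_hw_ms is None and self.observed_sw_ms is None:
            raise ValueError("a timing sample needs at least one observation")
        for v in (self.observed_hw_ms, self.observed_sw_ms):
            if v is not None and v < 0:
                raise ValueError("observed times must be >= 0")


class FitError(ValueError):
    """Raised when the least-squares system is under-determined."""


def hw_features(task_or_n: Union[ChainTask, int], H: int, P: int) -> HwFeatures:
    """Features of the hardware model for a task of ``n`` anchors.

    The fixed-bound pipeline iterates ``min(i, H)`` predecessors for
    anchor i (no start-window shortcut in hardware), so
    ``total_subparts = sum_i ceil(min(i, H) / P)``.
    """
    if P < 1:
        raise ValueError(f"P must be >= 1, got {P}")
    n = task_or_n if isinstance(task_or_n, int) else task_or_n.n
    if n <= 1:
        return HwFeatures(n=n, total_subparts=0)
    i = np.arange(n, dtype=np.int64)
    trips = np.minimum(i, H)
    total = int(np.sum((trips + P - 1) // P))
    return HwFeatures(n=n, total_subparts=total)


def sw_features(dp_or_task: Union[DPResult, ChainTask], params: ChainingParams | None = None) -> SwFeatures:
    """Software-model features: the summed inner-loop trip counts of the DP."""
    if isinstance(dp_or_task, ChainTask):
        dp = chain_scores(dp_or_task, params or ChainingParams())
    else:
        dp = dp_or_task
    return SwFeatures(sum_trip_count=int(dp.trip_count.sum()))


def predict_hw(feat: HwFeatures, c: PerfCoeffs) -> float:
    """Predicted hardware time in ms (transfer + execution + overhead, >= 0)."""
    return max(0.0, c.K1 * feat.n + c.E * feat.total_subparts + c.C1)


def predict_sw(feat: SwFeatures, c: PerfCoeffs) -> float:
    """Predicted software time in ms (>= 0)."""
    return max(0.0, c.K2 * feat.sum_trip_count + c.C2)


def fit_coeffs(
    samples: Sequence[TimingSample],
    which: Literal["hardware", "software"],
    base: PerfCoeffs | None = None,
    II: float = DEFAULT_II,
) -> PerfCoeffs:
    """Ordinary least squares fit of one predictor's coefficients.

    ``which="hardware"`` fits (K1, E, C1) against observed hardware times;
    ``which="software"`` fits (K2, C2) against observed software times.
    Requires at least two more usable samples than free parameters and a
    full-rank design matrix.  The residual RMS is recorded on the result.
    """
    if which == "hardware":
        rows = [
            ((s.n, s.total_subparts, 1.0), s.observed_hw_ms)
            for s in samples
            if s.observed_hw_ms is not None
        ]
        n_params = 3
    elif which == "software":
        rows = [
            ((s.sum_trip_count, 1.0), s.observed_sw_ms)
            for s in samples
            if s.observed_sw_ms is not None
        ]
        n_params = 2
    else:
        raise ValueError(f"which must be 'hardware' or 'software', got {which!r}")
    if len(rows) < n_params + 2:
        raise FitError(
            f"{which} fit needs >= {n_params + 2} samples with observations, got {len(rows)}"
        )
    X = np.array([r[0] for r in rows], dtype=np.float64)
    y = np.array([r[1] for r in rows], dtype=np.float64)
    if np.linalg.matrix_rank(X) < n_params:
        raise FitError(f"{which} fit design matrix is rank-deficient (collinear features)")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rms = float(np.sqrt(np.mean((X @ coef - y) ** 2)))
    out = base or PerfCoeffs()
    if which == "hardware":
        K1, E, C1 = (float(v) for v in coef)
        return replace(out, K1=K1, II=II, T_clock=E / II, C1=C1, residual_rms_hw=rms)
    K2, C2 = (float(v) for v in coef)
    return replace(out, K2=K2, C2=C2, residual_rms_sw=rms)


def synthesize_timings(
    features: Iterable[tuple[HwFeatures, SwFeatures]],
    coeffs: PerfCoeffs,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[TimingSample]:
    """Generate timing samples from a ground-truth model, optionally with
    multiplicative Gaussian noise (deterministic CI substitute for
    wall-clock calibration runs)."""
    rng = np.random.default_rng(seed)
    out = []
    for idx, (hw, sw) in enumerate(features):
        t_hw = predict_hw(hw, coeffs)
        t_sw = predict_sw(sw, coeffs)
        if noise_sigma > 0:
            t_hw *= max(0.0, 1.0 + noise_sigma * rng.standard_normal())
            t_sw *= max(0.0, 1.0 + noise_sigma * rng.standard_normal())
        out.append(
            TimingSample(
                n=hw.n,
                total_subparts=hw.total_subparts,
                sum_trip_count=sw.sum_trip_count,
                observed_hw_ms=t_hw,
                observed_sw_ms=t_sw,
                task_id=f"synth{idx:05d}",
            )
        )
    return out


def measure_software_times(
    tasks: Sequence[ChainTask], params: ChainingParams, repeats: int = 1
) -> list[TimingSample]:
    """Wall-clock software calibration sampler (software side only —
    there is no hardware to measure here).  Not used in tests."""
    out = []
    for task in tasks:
        hw = hw_features(task, params.H, params.P)
        best = math.inf
        dp = chain_scores(task, params)
        for _ in range(repeats):
            t0 = time.perf_counter()
            chain_scores(task, params)
            best = min(best, (time.perf_counter() - t0) * 1e3)
        out.append(
            TimingSample(
                n=task.n,
                total_subparts=hw.total_subparts,
                sum_trip_count=int(dp.trip_count.sum()),
                observed_sw_ms=best,
                task_id=task.task_id,
            )
        )
    return out


def _fmt_opt(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def write_timing_table(samples: Iterable[TimingSample], destination: Union[str, Path, IO[str]]) -> None:
    def _emit(fh: IO[str]) -> None:
        fh.write(TIMING_HEADER + "\n")
        for s in samples:
            fh.write(
                f"{s.task_id}\t{s.n}\t{s.total_subparts}\t{s.sum_trip_count}\t"
                f"{_fmt_opt(s.observed_hw_ms)}\t{_fmt_opt(s.observed_sw_ms)}\n"
            )

    if hasattr(destination, "write"):
        _emit(destination)  # type: ignore[arg-type]
    else:
        with open(destination, "w") as fh:
            _emit(fh)


def read_timing_table(source: Union[str, Path, IO[str]]) -> list[TimingSample]:
    def _parse(fh: IO[str]) -> list[TimingSample]:
        header = fh.readline().rstrip("\n")
        if header and header != TIMING_HEADER:
            raise ValueError(f"unexpected timing table header: {header!r}")
        out = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"line {lineno}: expected 6 fields, got {len(parts)}")
            task_id, n, subp, trips, hw_ms, sw_ms = parts
            out.append(
                TimingSample(
                    n=int(n),
                    total_subparts=int(subp),
                    sum_trip_count=int(trips),
                    observed_hw_ms=float(hw_ms) if hw_ms else None,
                    observed_sw_ms=float(sw_ms) if sw_ms else None,
                    task_id=task_id,
                )
            )
        return out

    if hasattr(source, "read"):
        return _parse(source)  # type: ignore[arg-type]
    with open(source) as fh:
        return _parse(fh)


def write_coeffs(coeffs: PerfCoeffs, destination: Union[str, Path, IO[str]]) -> None:
    """Write the flat key-value coefficients file."""
    pairs = [
        ("K1", repr(coeffs.K1)),
        ("E", repr(coeffs.E)),
        ("C1", repr(coeffs.C1)),
        ("K2", repr(coeffs.K2)),
        ("C2", repr(coeffs.C2)),
        ("II", repr(coeffs.II)),
        ("residual_rms_hw", _fmt_opt(coeffs.residual_rms_hw)),
        ("residual_rms_sw", _fmt_opt(coeffs.residual_rms_sw)),
    ]

    def _emit(fh: IO[str]) -> None:
        for key, val in pairs:
            fh.write(f"{key}\t{val}\n")

    if hasattr(destination, "write"):
        _emit(destination)  # type: ignore[arg-type]
    else:
        with open(destination, "w") as fh:
            _emit(fh)


def read_coeffs(source: Union[str, Path, IO[str]]) -> PerfCoeffs:
    def _parse(fh: IO[str]) -> PerfCoeffs:
        kv: dict[str, str] = {}
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("\t")
            kv[key.strip()] = val.strip()
        II = float(kv.get("II", DEFAULT_II))
        E = float(kv.get("E", "0"))
        return PerfCoeffs(
            K1=float(kv.get("K1", "0")),
            C1=float(kv.get("C1", "0")),
            II=II,
            T_clock=E / II if II > 0 else 0.0,
            K2=float(kv.get("K2", "0")),
            C2=float(kv.get("C2", "0")),
            residual_rms_hw=float(kv["residual_rms_hw"]) if kv.get("residual_rms_hw") else None,
            residual_rms_sw=float(kv["residual_rms_sw"]) if kv.get("residual_rms_sw") else None,
        )

    if hasattr(source, "read"):
        return _parse(source)  # type: ignore[arg-type]
    with open(source) as fh:
        return _parse(fh)
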