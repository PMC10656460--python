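"""Agreement between bounded-lookback and exact chaining.

A small trip-count bound can change both the best chain score and the
identity of the top chain; these measures quantify that at the chain
level, per task and aggregated over a batch of tasks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

from .anchors import ChainTask
from .chaining import (
    UNBOUNDED,
    Chain,
    ChainingParams,
    backtrack_chains,
    chain_scores,
)

__all__ = ["ConcordanceRow", "ConcordanceSummary", "compare_bounded", "aggregate"]


@dataclass(frozen=True)
class ConcordanceRow:
    task_id: str
    H: int
    best_score_bounded: float
    best_score_exact: float
    score_ratio: float
    identical_top_chain: bool


@dataclass(frozen=True)
class ConcordanceSummary:
    """Per-H means over a batch of rows."""

    H_values: tuple[int, ...]
    mean_score_ratio: dict[int, float]
    fraction_identical_top_chain: dict[int, float]
    fraction_ratio_one: dict[int, float]


def _best_and_top(task: ChainTask, params: ChainingParams) -> tuple[float, Chain]:
    """Best DP score and top chain under relaxed filters (min_score=0,
    min_cnt=1) so short tasks are not censored by reporting thresholds."""
    relaxed = dataclasses.replace(params, min_score=0.0, min_cnt=1)
    dp = chain_scores(task, relaxed)
    chains = backtrack_chains(task, dp, relaxed)
    return float(dp.f.max()), chains[0]


def compare_bounded(
    task: ChainTask, params: ChainingParams, H_list: Sequence[int]
) -> list[ConcordanceRow]:
    """One row per bound in ``H_list`` comparing against the exact DP."""
    if task.n == 0:
        return []
    best_exact, exact_top = _best_and_top(task, dataclasses.replace(params, H=UNBOUNDED))
    rows = []
    for H in H_list:
        best_bounded, bounded_top = _best_and_top(task, dataclasses.replace(params, H=H))
        rows.append(
            ConcordanceRow(
                task_id=task.task_id,
                H=H,
                best_score_bounded=best_bounded,
                best_score_exact=best_exact,
                score_ratio=best_bounded / best_exact,
                identical_top_chain=(
                    bounded_top.anchor_indices == exact_top.anchor_indices
                ),
            )
        )
    return rows


def aggregate(rows: Sequence[ConcordanceRow]) -> ConcordanceSummary:
    """Per-H arithmetic means and fractions over tasks."""
    if not rows:
        raise ValueError("cannot aggregate an empty row list")
    by_h: dict[int, list[ConcordanceRow]] = {}
    for row in rows:
        by_h.setdefault(row.H, []).append(row)
    H_values = tuple(sorted(by_h))
    mean_ratio = {}
    frac_identical = {}
    frac_one = {}
    for H, grp in by_h.items():
        mean_ratio[H] = sum(r.score_ratio for r in grp) / len(grp)
        frac_identical[H] = sum(r.identical_top_chain for r in grp) / len(grp)
        frac_one[H] = sum(r.score_ratio == 1.0 for r in grp) / len(grp)
    return ConcordanceSummary(
        H_values=H_values,
        mean_score_ratio=mean_ratio,
        fraction_identical_top_chain=frac_identical,
        fraction_ratio_one=frac_one,
    )
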