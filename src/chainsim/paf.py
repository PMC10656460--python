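"""Minimal PAF emission for backtracked chains.

Internal anchor coordinates are 0-based inclusive ends; PAF wants 0-based
half-open intervals, so a chain spanning anchors ``first..last`` maps to
``start = end_first - w_first + 1`` and ``open end = end_last + 1`` on
both axes.  MAPQ is fixed at 255 (unknown).
"""

from __future__ import annotations

from .anchors import ChainTask
from .chaining import Chain

__all__ = ["chain_to_paf_row", "chains_to_paf"]


def chain_to_paf_row(
    task: ChainTask,
    chain: Chain,
    query_name: str,
    query_length: int,
    target_name: str,
    target_length: int,
) -> str:
    first = task.anchors[chain.anchor_indices[0]]
    last = task.anchors[chain.anchor_indices[-1]]
    q_start = first.y - first.w + 1
    q_end = last.y + 1
    t_start = first.x - first.w + 1
    t_end = last.x + 1
    block_len = max(q_end - q_start, t_end - t_start)
    n_match = min(sum(task.anchors[i].w for i in chain.anchor_indices), block_len)
    fields = (
        query_name,
        query_length,
        q_start,
        q_end,
        task.strand,
        target_name,
        target_length,
        t_start,
        t_end,
        n_match,
        block_len,
        255,
    )
    return "\t".join(str(v) for v in fields)


def chains_to_paf(
    task: ChainTask,
    chains: list[Chain],
    query_name: str,
    query_length: int,
    target_name: str,
    target_length: int,
) -> list[str]:
    return [
        chain_to_paf_row(task, c, query_name, query_length, target_name, target_length)
        for c in chains
    ]
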