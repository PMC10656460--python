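"""Minimizer sampling and shared-minimizer anchor extraction.

Keys are canonical: the 2-bit encoding (A=0, C=1, G=2, T=3) of the
lexicographically smaller of a k-mer and its reverse complement.  No hash
scramble is applied, so keys are invertible and directly testable.
Window ties break to the leftmost position.
"""

from __future__ import annotations

from collections import deque
from pathlib import Path
from typing import NamedTuple

from Bio import SeqIO

from .anchors import Anchor, ChainTask

__all__ = ["Minimizer", "minimizers", "extract_anchors", "read_fasta"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class Minimizer(NamedTuple):
    pos: int  # start position of the k-mer
    key: int  # canonical 2-bit key
    strand: str  # orientation that won: '+' forward, '-' reverse complement


def _kmer_keys(sequence: str, k: int) -> list[tuple[int, int, str] | None]:
    """Per-start (pos, canonical key, strand), or None where the k-mer has an N."""
    seq = sequence.upper()
    n = len(seq)
    out: list[tuple[int, int, str] | None] = []
    mask = (1 << (2 * k)) - 1
    fwd = rev = 0
    valid = 0  # run length of non-N bases ending at current position
    shift = 2 * (k - 1)
    for i, base in enumerate(seq):
        code = _CODE.get(base)
        if code is None:
            valid, fwd, rev = 0, 0, 0
        else:
            fwd = ((fwd << 2) | code) & mask
            rev = (rev >> 2) | ((3 - code) << shift)
            valid += 1
        if i >= k - 1:
            if valid >= k:
                if fwd <= rev:
                    out.append((i - k + 1, fwd, "+"))
                else:
                    out.append((i - k + 1, rev, "-"))
            else:
                out.append(None)
    return out


def minimizers(sequence: str, k: int, wmin: int) -> list[Minimizer]:
    """Sample minimizers: for every window of ``wmin`` consecutive k-mers,
    the valid k-mer with the smallest canonical key (leftmost on ties).

    k-mers containing ``N`` are skipped; duplicate positions selected by
    overlapping windows are reported once.  Sequences shorter than ``k``
    yield an empty list.
    """
    if k < 1 or wmin < 1:
        raise ValueError(f"k and wmin must be >= 1, got k={k}, wmin={wmin}")
    keys = _kmer_keys(sequence, k)
    n_kmers = len(keys)
    if n_kmers == 0:
        return []
    out: list[Minimizer] = []
    seen: set[int] = set()
    window: deque[tuple[int, int, str]] = deque()  # ascending pos, non-decreasing key
    span = min(wmin, n_kmers)
    for i in range(n_kmers):
        entry = keys[i]
        if entry is not None:
            # keep earlier entries on equal keys: leftmost wins ties
            while window and window[-1][1] > entry[1]:
                window.pop()
            window.append(entry)
        lo = i - span + 1
        while window and window[0][0] < lo:
            window.popleft()
        if i >= span - 1 and window:
            pos, key, strand = window[0]
            if pos not in seen:
                seen.add(pos)
                out.append(Minimizer(pos, key, strand))
    return out


def extract_anchors(
    reference: str,
    read: str,
    k: int = 15,
    wmin: int = 10,
    task_id: str = "read",
) -> dict[str, ChainTask]:
    """Build per-strand chaining tasks from shared minimizer keys.

    Reference minimizers are indexed by key; each read minimizer with a
    matching key emits ``Anchor(x=ref k-mer end, y=read k-mer end, w=k)``
    on the strand implied by the orientation pair.  Reverse-strand anchors
    use flipped read coordinates so chaining is always forward-monotone.
    """
    index: dict[int, list[tuple[int, str]]] = {}
    for pos, key, strand in minimizers(reference, k, wmin):
        index.setdefault(key, []).append((pos, strand))
    read_len = len(read)
    per_strand: dict[str, set[Anchor]] = {"+": set(), "-": set()}
    for rpos, key, rstrand in minimizers(read, k, wmin):
        for tpos, tstrand in index.get(key, ()):
            rel = "+" if rstrand == tstrand else "-"
            x = tpos + k - 1
            if rel == "+":
                y = rpos + k - 1
            else:
                y = read_len - 1 - rpos  # end position on the flipped read
            per_strand[rel].add(Anchor(x, y, k))
    return {
        strand: ChainTask(
            task_id=f"{task_id}:{strand}",
            anchors=tuple(sorted(anchors, key=lambda a: (a.x, a.y))),
            query_length=read_len,
            strand=strand,
        )
        for strand, anchors in per_strand.items()
    }


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, wrapped) FASTA file as (name, sequence)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
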