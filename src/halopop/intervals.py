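"""Interval arithmetic on 0-based half-open coordinates."""

from __future__ import annotations

from typing import Iterable, Sequence

from .genomics_io import Interval

__all__ = ["merge_intervals", "union_length", "complement_intervals"]


def merge_intervals(intervals: Iterable[Interval], gap: int = 0) -> list[Interval]:
    """Merge overlapping (or within `gap` bp) intervals per sequence.

    Result is sorted by (seq_id, start) and pairwise disjoint.
    """
    by_seq: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    merged: list[Interval] = []
    for sid in sorted(by_seq):
        ivs = sorted(by_seq[sid], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + gap:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(sid, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(sid, cur_start, cur_end))
    return merged


def union_length(intervals: Iterable[Interval]) -> int:
    """Total bp covered by the union of the intervals."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def complement_intervals(
    intervals: Sequence[Interval], seq_id: str, length: int
) -> list[Interval]:
    """Complement of the union of `intervals` within [0, length) of seq_id."""
    merged = [iv for iv in merge_intervals(intervals) if iv.seq_id == seq_id]
    out: list[Interval] = []
    pos = 0
    for iv in merged:
        if iv.start > pos:
            out.append(Interval(seq_id, pos, iv.start))
        pos = max(pos, iv.end)
    if pos < length:
        out.append(Interval(seq_id, pos, length))
    return out
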