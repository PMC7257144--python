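"""Small shared helpers: interval arithmetic and transparent file opening."""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Iterable, TextIO

Interval = tuple[int, int]  # 1-based inclusive


def open_text(path: str | Path) -> TextIO:
    """Open a possibly gzip-compressed text file for reading."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of 1-based inclusive intervals; adjacent intervals are joined."""
    merged: list[Interval] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def complement_intervals(span: Interval, intervals: list[Interval]) -> list[Interval]:
    """Gaps of `intervals` (assumed merged, sorted) inside `span`."""
    gaps: list[Interval] = []
    cursor = span[0]
    for start, end in intervals:
        if start > cursor:
            gaps.append((cursor, start - 1))
        cursor = max(cursor, end + 1)
    if cursor <= span[1]:
        gaps.append((cursor, span[1]))
    return gaps


def interval_bases(intervals: Iterable[Interval]) -> int:
    return sum(end - start + 1 for start, end in intervals)
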