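"""Placement-based microhomology primitive.

The microhomology of a deletion is defined operationally as the number of
distinct placements of an equal-length deletion that produce the identical
repaired sequence, minus one.  That count decomposes into the number of
single-base shifts available to the left plus the number available to the
right of the given placement, which is what is computed here.
"""

from __future__ import annotations


def mh_extensions(seq: str, start: int, end: int) -> tuple[int, int]:
    """Left/right shift counts for the deletion of seq[start..end] (1-based).

    A shift right by one is valid iff seq[start] == seq[end+1] (0-based:
    seq[start-1] == seq[end]); shifts chain base by base.
    """
    n = len(seq)
    if not (1 <= start <= end <= n):
        raise ValueError(f"deletion {start}..{end} out of range 1..{n}")
    s, e = start - 1, end  # 0-based: deleted slice seq[s:e]
    right = 0
    while e + right < n and seq[s + right] == seq[e + right]:
        right += 1
    left = 0
    while s - left - 1 >= 0 and seq[s - left - 1] == seq[e - left - 1]:
        left += 1
    return left, right


def placement_mh(seq: str, start: int, end: int) -> int:
    left, right = mh_extensions(seq, start, end)
    return left + right
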