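"""Amplicon read processing: merge, align, extract and group repair events.

Alignment is global in the read with affine gap penalties (defaults: match +2,
mismatch -4, gap open -6 covering the first gap base, extend -1 per further
base).  Indels are left-aligned after alignment so that every equivalent
placement of the same event maps to one canonical group key.  Reads whose
global alignment scores poorly (large structural change) are routed through an
anchor-based realignment that admits one large gap, replacing the soft-clip
realignment stage of SAM-based pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .constructs import AmpliconRef

DELETION_ONLY = "deletion_only"
INSERTION_ONLY = "insertion_only"
DELETION_AND_INSERTION = "deletion_and_insertion"
SOFT_CLIPPED = "soft_clipped"
REFERENCE = "reference"

READ_CLASSES = (DELETION_ONLY, INSERTION_ONLY, DELETION_AND_INSERTION, SOFT_CLIPPED)


@dataclass
class AlignConfig:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6  # cost of a length-1 gap
    gap_extend: int = -1  # each additional gap base
    min_score_frac: float = 0.4  # flag alignments below this fraction of max
    min_anchor: int = 20  # exact seed length for large-gap realignment
    max_global_cells: int = 8_000_000  # DP size guard for full realignment


@dataclass
class MergedRead:
    id: str
    sequence: str
    quality: list[int] | None = None
    provenance: str = "single"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")


@dataclass
class RepairEvent:
    kind: str  # "del" | "ins"
    read_id: str
    start: int = 0  # del: 1-based inclusive
    end: int = 0
    pos: int = 0  # ins: 1-based ref base immediately left of the insertion
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.kind == "del":
            if self.start > self.end:
                raise ValueError("deletion start must be <= end")
        elif self.kind == "ins":
            if not self.sequence:
                raise ValueError("insertion sequence must be non-empty")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1 if self.kind == "del" else len(self.sequence)

    @property
    def key(self) -> tuple:
        if self.kind == "del":
            return ("del", self.start, self.end)
        return ("ins", self.pos, len(self.sequence), self.sequence)


@dataclass
class AlignmentResult:
    reference_name: str
    read_id: str
    read_seq: str
    ref_seq: str
    ops: list[tuple[str, int]]  # (op, length); op in M I D S
    ref_start: int  # 1-based
    score: float
    low_score: bool = False

    def __post_init__(self) -> None:
        read_span = sum(n for op, n in self.ops if op in "MIS")
        ref_span = sum(n for op, n in self.ops if op in "MD")
        if read_span != len(self.read_seq):
            raise ValueError("ops do not span the read")
        if self.ref_start - 1 + ref_span > len(self.ref_seq):
            raise ValueError("ops overrun the reference")

    @property
    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)

    def has_clip(self) -> bool:
        return any(op == "S" for op, _ in self.ops)


@dataclass
class EventGroup:
    key: tuple
    kind: str
    count: int
    read_ids: list[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.key[1] if self.kind == "del" else 0

    @property
    def end(self) -> int:
        return self.key[2] if self.kind == "del" else 0

    @property
    def pos(self) -> int:
        return self.key[1] if self.kind == "ins" else 0

    @property
    def sequence(self) -> str:
        return self.key[3] if self.kind == "ins" else ""

    @property
    def length(self) -> int:
        return self.key[2] - self.key[1] + 1 if self.kind == "del" else self.key[2]


# ---------------------------------------------------------------------------
# merging


def merge_pairs(
    read1: MergedRead,
    read2: MergedRead,
    min_overlap: int = 10,
    max_mismatch_rate: float = 0.1,
) -> MergedRead | None:
    """Overlap-merge a forward/reverse pair; None when no acceptable overlap.

    The reverse read is reverse-complemented, the longest suffix/prefix
    overlap within the mismatch budget is used, and disagreements resolve to
    the higher-quality base (first read wins ties).
    """
    from ._seq import revcomp

    s1, q1 = read1.sequence.upper(), read1.quality
    s2 = revcomp(read2.sequence.upper())
    q2 = read2.quality[::-1] if read2.quality is not None else None
    best = None
    for olap in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        a, b = s1[-olap:], s2[:olap]
        mism = sum(x != y for x, y in zip(a, b))
        if mism <= max_mismatch_rate * olap:
            best = olap
            break
    if best is None:
        return None
    head = s1[: len(s1) - best]
    tail = s2[best:]
    overlap_bases = []
    for i in range(best):
        x, y = s1[len(s1) - best + i], s2[i]
        if x == y:
            overlap_bases.append(x)
        else:
            qx = q1[len(s1) - best + i] if q1 is not None else 0
            qy = q2[i] if q2 is not None else 0
            overlap_bases.append(y if qy > qx else x)
    merged_q = None
    if q1 is not None and q2 is not None:
        merged_q = (
            q1[: len(s1) - best]
            + [max(q1[len(s1) - best + i], q2[i]) for i in range(best)]
            + q2[best:]
        )
    return MergedRead(
        id=read1.id,
        sequence=head + "".join(overlap_bases) + tail,
        quality=merged_q,
        provenance="merged-pair",
    )


# ---------------------------------------------------------------------------
# alignment


def _make_aligner(config: AlignConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    return aligner


def _ops_from_alignment(alignment, ref_len: int, read_len: int) -> list[tuple[str, int]]:
    """Convert Biopython aligned blocks to an M/I/D op list (global mode)."""
    t_blocks, q_blocks = alignment.aligned
    ops: list[tuple[str, int]] = []
    t_prev = 0
    q_prev = 0

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        push("D", ts - t_prev)
        push("I", qs - q_prev)
        push("M", te - ts)
        t_prev, q_prev = te, qe
    push("D", ref_len - t_prev)
    push("I", read_len - q_prev)
    return ops


def align_read(
    read: MergedRead | str,
    ref: AmpliconRef,
    config: AlignConfig | None = None,
) -> AlignmentResult:
    """Global affine-gap alignment of one read against the amplicon reference.

    Low-scoring reads are flagged (``low_score``), never dropped.
    """
    config = config or AlignConfig()
    if isinstance(read, str):
        read = MergedRead(id="read", sequence=read)
    aligner = _make_aligner(config)
    alignment = aligner.align(ref.sequence, read.sequence.upper())[0]
    ops = _ops_from_alignment(alignment, len(ref.sequence), len(read.sequence))
    score = float(alignment.score)
    return AlignmentResult(
        reference_name=ref.name,
        read_id=read.id,
        read_seq=read.sequence.upper(),
        ref_seq=ref.sequence,
        ops=ops,
        ref_start=1,
        score=score,
        low_score=score < config.min_score_frac * config.match * len(read.sequence),
    )


def _extend_forward(read: str, ref: str, r0: int) -> int:
    n = 0
    while n < len(read) and r0 + n < len(ref) and read[n] == ref[r0 + n]:
        n += 1
    return n


def _extend_backward(read: str, ref: str) -> int:
    n = 0
    while (
        n < len(read)
        and n < len(ref)
        and read[len(read) - 1 - n] == ref[len(ref) - 1 - n]
    ):
        n += 1
    return n


def realign_softclip(
    read: MergedRead | str,
    ref: AmpliconRef,
    prior: AlignmentResult | None = None,
    config: AlignConfig | None = None,
) -> AlignmentResult | None:
    """End-to-end realignment admitting one large gap.

    Anchors the read with exact seed matches at both ends, extends them, and
    bridges the remainder with a single deletion and/or insertion.  A prior
    alignment without clipping and with an acceptable score is returned
    unchanged.  Returns None for irrecoverable reads.
    """
    config = config or AlignConfig()
    if isinstance(read, str):
        read = MergedRead(id="read", sequence=read)
    if prior is not None and not prior.has_clip() and not prior.low_score:
        return prior
    seq = read.sequence.upper()
    refseq = ref.sequence
    k = config.min_anchor
    if len(seq) < 2 * k:
        return _fallback_global(read, ref, config)

    left_at = refseq.find(seq[:k])
    right_at = refseq.rfind(seq[-k:])
    if left_at < 0 or right_at < 0:
        return _fallback_global(read, ref, config)
    xl = _extend_forward(seq, refseq, left_at)  # read prefix length matched
    back = _extend_backward(seq, refseq[: right_at + k])
    yr = len(seq) - back  # 0-based read index where the right anchor starts
    o_r = right_at + k - back  # 0-based ref index aligned to read[yr]

    # keep the split leftmost: trim the left anchor where the anchors overlap
    # in the read, then where they overlap in the reference
    xl = min(xl, yr)
    if o_r - left_at < xl:
        xl = o_r - left_at
    if xl < 0:
        return _fallback_global(read, ref, config)
    g_read = yr - xl
    g_ref = o_r - (left_at + xl)
    if g_ref < 0:
        return _fallback_global(read, ref, config)

    ops: list[tuple[str, int]] = []
    if xl:
        ops.append(("M", xl))
    if g_ref:
        ops.append(("D", g_ref))
    if g_read:
        ops.append(("I", g_read))
    if len(seq) - yr:
        ops.append(("M", len(seq) - yr))

    def gap_cost(g: int) -> int:
        return 0 if g == 0 else -(config.gap_open + (g - 1) * config.gap_extend)

    score = config.match * (xl + len(seq) - yr) - gap_cost(g_ref) - gap_cost(g_read)
    return AlignmentResult(
        reference_name=ref.name,
        read_id=read.id,
        read_seq=seq,
        ref_seq=refseq,
        ops=ops,
        ref_start=left_at + 1,
        score=float(score),
        low_score=False,
    )


def _fallback_global(
    read: MergedRead, ref: AmpliconRef, config: AlignConfig
) -> AlignmentResult | None:
    if len(read.sequence) * len(ref.sequence) > config.max_global_cells:
        return None
    return align_read(read, ref, config)


# ---------------------------------------------------------------------------
# event extraction and grouping


def _left_align_deletion(ref: str, start: int, end: int) -> tuple[int, int]:
    length = end - start + 1
    while start > 1 and ref[start - 2] == ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def _left_align_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    while pos > 0 and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def extract_events(aln: AlignmentResult) -> tuple[str, list[RepairEvent]]:
    """Read class plus one left-aligned RepairEvent per indel operation."""
    events: list[RepairEvent] = []
    clipped = False
    ref_pos = aln.ref_start - 1  # 0-based
    read_pos = 0
    for op, n in aln.ops:
        if op == "M":
            ref_pos += n
            read_pos += n
        elif op == "D":
            start, end = _left_align_deletion(aln.ref_seq, ref_pos + 1, ref_pos + n)
            events.append(
                RepairEvent(kind="del", read_id=aln.read_id, start=start, end=end)
            )
            ref_pos += n
        elif op == "I":
            seq = aln.read_seq[read_pos : read_pos + n]
            pos, seq = _left_align_insertion(aln.ref_seq, ref_pos, seq)
            events.append(
                RepairEvent(kind="ins", read_id=aln.read_id, pos=pos, sequence=seq)
            )
            read_pos += n
        elif op == "S":
            clipped = True
            read_pos += n
        else:
            raise ValueError(f"unknown op {op!r}")
    if clipped:
        return SOFT_CLIPPED, events
    has_del = any(e.kind == "del" for e in events)
    has_ins = any(e.kind == "ins" for e in events)
    if has_del and has_ins:
        return DELETION_AND_INSERTION, events
    if has_del:
        return DELETION_ONLY, events
    if has_ins:
        return INSERTION_ONLY, events
    return REFERENCE, events


def group_events(events: Iterable[RepairEvent]) -> list[EventGroup]:
    """Group left-aligned events by canonical key with supporting-read counts."""
    groups: dict[tuple, EventGroup] = {}
    for ev in events:
        g = groups.get(ev.key)
        if g is None:
            g = EventGroup(key=ev.key, kind=ev.kind, count=0)
            groups[ev.key] = g
        g.count += 1
        g.read_ids.append(ev.read_id)
    return sorted(groups.values(), key=lambda g: g.key)


def write_sam(alignments: Sequence[AlignmentResult], ref: AmpliconRef, path) -> None:
    """Optional SAM export of alignments for inspection."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.name, "LN": len(ref.sequence)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.read_seq
            seg.reference_id = 0
            seg.reference_start = aln.ref_start - 1
            seg.mapping_quality = 0 if aln.low_score else 60
            seg.cigarstring = aln.cigar
            out.write(seg)
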