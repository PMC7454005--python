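"""Junction analytics: microhomology, TMEJ calls, noise filtering, insertion origins.

Deletion microhomology is the placement count minus one: the number of
equal-length deletions of the reference producing the identical repaired
sequence.  Deletions whose MH falls in the configured window (default 3-6 bp)
carry the polymerase-theta end-joining flag.  Event groups are filtered
against a Poisson background model ("confidence interval" cutoff at 90/95/99%
depending on sample).  Insertions of 5-15 bp are assigned a template origin
class (distant / nearby / snapback / direct_repeat / random) by exhaustive
full-length search over both strands of the supplied references; shorter
insertions use the three-way template / snapback / undetermined scheme.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import poisson

from ._mh import placement_mh
from ._seq import revcomp
from .constructs import JunctionCoord
from .pipeline import EventGroup

TMEJ_WINDOW = (3, 6)
ORIGIN_CLASSES = ("distant", "nearby", "snapback", "direct_repeat", "random")
_PRECEDENCE = ("direct_repeat", "snapback", "nearby", "distant")
SHORT_CLASSES = ("template", "snapback", "undetermined")
EXCLUDED = "excluded"

MIN_MH_CALL = 2  # minimum priming/joining MH reported (POLQ needs >= 2 bp)
MAX_MH_CALL = 6


def deletion_microhomology(ref: str, del_start: int, del_end: int) -> int:
    """MH length for the deletion of ref[del_start..del_end] (1-based)."""
    return placement_mh(ref.upper(), del_start, del_end)


def call_tmej(mh_length: int, window: tuple[int, int] = TMEJ_WINDOW) -> bool:
    lo, hi = window
    return lo <= mh_length <= hi


@dataclass
class DeletionCall:
    group: EventGroup
    mh_length: int
    tmej: bool

    def __post_init__(self) -> None:
        if self.mh_length < 0:
            raise ValueError("mh_length must be >= 0")


@dataclass(frozen=True)
class OriginHit:
    ref_name: str
    strand: str  # "+" | "-"
    start: int  # 1-based leftmost coordinate on the forward strand
    end: int


@dataclass
class InsertionCall:
    group: EventGroup
    origin_class: str | None = None  # five-way class, EXCLUDED, or None
    short_class: str | None = None  # three-way class for short insertions
    origin: OriginHit | None = None
    candidates: tuple[OriginHit, ...] = ()
    mh_init: int = 0
    mh_end: int = 0


@dataclass
class NoiseModel:
    lam: float
    level: float
    cutoff: int

    def __post_init__(self) -> None:
        if self.cutoff < 1:
            raise ValueError("cutoff must be >= 1")


def estimate_background(
    groups: Sequence[EventGroup], strategy: str = "median_trimmed"
) -> float:
    """Expected background support per spurious event group.

    Default: mean supporting-read count over groups at or below the median
    count, which is robust to a handful of genuine high-support events.
    """
    if not groups:
        raise ValueError("no event groups to estimate background from")
    counts = sorted(g.count for g in groups)
    if strategy == "median_trimmed":
        median = counts[(len(counts) - 1) // 2]
        kept = [c for c in counts if c <= median]
        return sum(kept) / len(kept)
    if strategy == "mean":
        return sum(counts) / len(counts)
    raise ValueError(f"unknown strategy {strategy!r}")


def poisson_cutoff(lam: float, level: float) -> int:
    """Smallest c >= 1 with P(X >= c | Poisson(lam)) <= 1 - level."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    return int(poisson.ppf(level, lam)) + 1 if lam > 0 else 1


def filter_noise(
    groups: Sequence[EventGroup],
    level: float = 0.95,
    lam: float | None = None,
    strategy: str = "median_trimmed",
) -> tuple[list[EventGroup], list[EventGroup], NoiseModel]:
    """Split groups into (retained, background) at the Poisson cutoff."""
    if lam is None:
        lam = estimate_background(groups, strategy=strategy)
    cutoff = poisson_cutoff(lam, level)
    model = NoiseModel(lam=lam, level=level, cutoff=cutoff)
    kept = [g for g in groups if g.count >= cutoff]
    noise = [g for g in groups if g.count < cutoff]
    return kept, noise, model


def classify_deletions(
    groups: Iterable[EventGroup],
    ref: str,
    tmej_window: tuple[int, int] = TMEJ_WINDOW,
) -> list[DeletionCall]:
    calls = []
    for g in groups:
        if g.kind != "del":
            continue
        mh = deletion_microhomology(ref, g.start, g.end)
        calls.append(DeletionCall(group=g, mh_length=mh, tmej=call_tmej(mh, tmej_window)))
    return calls


# ---------------------------------------------------------------------------
# insertion origin classification


def _all_hits(seq: str, probe: str) -> list[int]:
    hits, at = [], seq.find(probe)
    while at >= 0:
        hits.append(at + 1)
        at = seq.find(probe, at + 1)
    return hits


def find_origin_hits(
    ins: str, refs: Sequence[tuple[str, str]]
) -> list[OriginHit]:
    """Exact full-length matches of the insertion over both strands of refs."""
    ins = ins.upper()
    rc = revcomp(ins)
    hits: list[OriginHit] = []
    for name, seq in refs:
        seq = seq.upper()
        for start in _all_hits(seq, ins):
            hits.append(OriginHit(name, "+", start, start + len(ins) - 1))
        if rc != ins:
            for start in _all_hits(seq, rc):
                hits.append(OriginHit(name, "-", start, start + len(ins) - 1))
    return hits


def _junction_gap(hit: OriginHit, junction_pos: int) -> int:
    """Bases between the hit segment and the junction boundary (0 if touching)."""
    boundary_left, boundary_right = junction_pos, junction_pos + 1
    if hit.start > boundary_left:
        return hit.start - boundary_right
    if hit.end < boundary_right:
        return boundary_left - hit.end
    return 0


def _hit_class(
    hit: OriginHit, junction_pos: int, primary_name: str, nearby_window: int
) -> str:
    if hit.ref_name != primary_name:
        return "distant"
    gap = _junction_gap(hit, junction_pos)
    if hit.strand == "+":
        if hit.end == junction_pos or hit.start == junction_pos + 1:
            return "direct_repeat"
        return "nearby" if gap < nearby_window else "distant"
    return "snapback" if gap < nearby_window else "distant"


def classify_insertion_origin(
    ins: str,
    junction_pos: int,
    primary_ref: tuple[str, str],
    extra_refs: Sequence[tuple[str, str]] = (),
    nearby_window: int = 100,
    length_bounds: tuple[int, int] = (5, 15),
    max_candidates: int = 1,
) -> tuple[str, list[OriginHit]]:
    """Five-way origin class for an insertion at ``junction_pos``.

    ``junction_pos`` is the 1-based reference base immediately left of the
    insertion in the primary reference.  Returns (class, candidate hits of the
    winning class); class is "random" with no hits, or "excluded" when the
    winning class is ambiguous (more than ``max_candidates`` distinct origins).
    """
    lo, hi = length_bounds
    if not lo <= len(ins) <= hi:
        raise ValueError(
            f"insertion length {len(ins)} outside origin-class bounds {lo}-{hi}"
        )
    refs = [primary_ref, *extra_refs]
    hits = find_origin_hits(ins, refs)
    if not hits:
        return "random", []
    by_class: dict[str, list[OriginHit]] = {}
    for h in hits:
        by_class.setdefault(
            _hit_class(h, junction_pos, primary_ref[0], nearby_window), []
        ).append(h)
    for cls in _PRECEDENCE:
        if cls in by_class:
            candidates = by_class[cls]
            if len(candidates) > max_candidates:
                return EXCLUDED, candidates
            return cls, candidates
    raise AssertionError("unreachable: hits must classify")


def classify_short_insertion(
    ins: str,
    junction_pos: int,
    ref: str,
    flank_window: int = 100,
) -> str:
    """Three-way class for insertions below the five-way minimum length.

    Searches the flanking windows either side of the junction for an exact
    match (template) or reverse-complement match (snapback); single-base
    insertions are below matchable specificity and always undetermined.
    """
    ins = ins.upper()
    if len(ins) <= 1:
        return "undetermined"
    ref = ref.upper()
    left = ref[max(0, junction_pos - flank_window) : junction_pos]
    right = ref[junction_pos : junction_pos + flank_window]
    flanks = left + "|" + right  # separator prevents matches across the break
    if ins in flanks:
        return "template"
    if revcomp(ins) in flanks:
        return "snapback"
    return "undetermined"


def insertion_mh_flags(
    ins: str,
    junction_pos: int,
    origin: OriginHit,
    ref_seqs: dict[str, str],
    primary_name: str,
    min_mh: int = MIN_MH_CALL,
    max_mh: int = MAX_MH_CALL,
) -> tuple[int, int]:
    """(mh_init, mh_end) for a templated insertion.

    mh_init: longest suffix of the upstream junction flank equal to the bases
    immediately 5' of the origin copy in template orientation (the priming
    microhomology).  mh_end: longest suffix of the inserted sequence equal to
    the leading bases of the downstream junction flank (the joining
    microhomology).  Values shorter than ``min_mh`` report 0.
    """
    ins = ins.upper()
    primary = ref_seqs[primary_name].upper()
    template = ref_seqs[origin.ref_name].upper()
    left_flank = primary[:junction_pos]
    right_flank = primary[junction_pos:]

    def before_origin(k: int) -> str | None:
        if origin.strand == "+":
            lo = origin.start - 1 - k
            return template[lo : lo + k] if lo >= 0 else None
        hi = origin.end + k
        return revcomp(template[origin.end : hi]) if hi <= len(template) else None

    mh_init = 0
    for k in range(1, max_mh + 1):
        probe = before_origin(k)
        if probe is None or len(left_flank) < k:
            break
        if left_flank[-k:] == probe:
            mh_init = k
    mh_end = 0
    for k in range(1, min(max_mh, len(ins), len(right_flank)) + 1):
        if ins[-k:] == right_flank[:k]:
            mh_end = k
    if mh_init < min_mh:
        mh_init = 0
    if mh_end < min_mh:
        mh_end = 0
    return mh_init, mh_end


def classify_insertions(
    groups: Iterable[EventGroup],
    primary_ref: tuple[str, str],
    extra_refs: Sequence[tuple[str, str]] = (),
    nearby_window: int = 100,
    length_bounds: tuple[int, int] = (5, 15),
    max_candidates: int = 1,
    min_mh: int = MIN_MH_CALL,
    max_mh: int = MAX_MH_CALL,
    coord_offset: int = 0,
) -> list[InsertionCall]:
    """Route insertion groups through the short or five-way classifier.

    ``coord_offset`` maps event positions into the primary reference when the
    aligned-to amplicon is a sub-region of it (construct position of amplicon
    base 1, minus 1).
    """
    lo, hi = length_bounds
    ref_seqs = {name: seq for name, seq in [primary_ref, *extra_refs]}
    calls = []
    for g in groups:
        if g.kind != "ins":
            continue
        call = InsertionCall(group=g)
        ins, jp = g.sequence, g.pos + coord_offset
        if len(ins) < lo:
            call.short_class = classify_short_insertion(
                ins, jp, primary_ref[1], flank_window=nearby_window
            )
        elif len(ins) > hi:
            call.origin_class = None  # reported unclassified (> upper bound)
        else:
            cls, candidates = classify_insertion_origin(
                ins,
                jp,
                primary_ref,
                extra_refs,
                nearby_window=nearby_window,
                length_bounds=length_bounds,
                max_candidates=max_candidates,
            )
            call.origin_class = cls
            call.candidates = tuple(candidates)
            if cls in ("distant", "nearby", "snapback", "direct_repeat"):
                call.origin = candidates[0]
                call.mh_init, call.mh_end = insertion_mh_flags(
                    ins,
                    jp,
                    call.origin,
                    ref_seqs,
                    primary_ref[0],
                    min_mh=min_mh,
                    max_mh=max_mh,
                )
        calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# summary tables


def _pct(n: int, total: int) -> float:
    return 100.0 * n / total if total else 0.0


def summarize_assay(
    n_precise: int,
    deletion_calls: Sequence[DeletionCall],
    insertion_calls: Sequence[InsertionCall],
    assay: str = "proximal",
) -> dict:
    """Per-sample frequency tables mirroring the figure panels.

    All percentages are read-supported fractions of the total counted product
    reads (precise + deletion + insertion supporting reads).
    """
    if assay not in ("proximal", "distal"):
        raise ValueError("assay must be 'proximal' or 'distal'")
    del_reads = sum(c.group.count for c in deletion_calls)
    ins_reads = sum(c.group.count for c in insertion_calls)
    total = n_precise + del_reads + ins_reads
    if total == 0:
        raise ValueError("no products to summarize")

    mh_hist = Counter()
    tmej_reads = 0
    for c in deletion_calls:
        mh_hist[min(c.mh_length, 7)] += c.group.count
        if c.tmej:
            tmej_reads += c.group.count
    ins_len_hist = Counter()
    origin_comp = Counter()
    hotspots = Counter()
    origin_positions = Counter()
    templated = [
        c
        for c in insertion_calls
        if c.origin_class in ("distant", "nearby", "snapback")
    ]
    mh_init_reads = mh_end_reads = mh_both_reads = templated_reads = 0
    for c in insertion_calls:
        ins_len_hist[min(c.group.length, 16)] += c.group.count
        label = c.origin_class if c.origin_class else f"short:{c.short_class}"
        origin_comp[label] += c.group.count
        hotspots[str(JunctionCoord.after(c.group.pos))] += c.group.count
    for c in templated:
        templated_reads += c.group.count
        if c.mh_init > 0:
            mh_init_reads += c.group.count
        if c.mh_end > 0:
            mh_end_reads += c.group.count
        if c.mh_init > 0 and c.mh_end > 0:
            mh_both_reads += c.group.count
        if c.origin is not None:
            origin_positions[(c.origin.ref_name, c.origin.strand, c.origin.start)] += (
                c.group.count
            )

    return {
        "assay": assay,
        "total_reads": total,
        "precise_pct": _pct(n_precise, total),
        "deletion_pct": _pct(del_reads, total),
        "insertion_pct": _pct(ins_reads, total),
        "tmej_pct": _pct(tmej_reads, total),
        "deletions_by_mh_pct": {
            (f"{k}" if k < 7 else "7+"): _pct(v, total) for k, v in sorted(mh_hist.items())
        },
        "insertions_by_length_pct": {
            (f"{k}" if k < 16 else "16+"): _pct(v, total)
            for k, v in sorted(ins_len_hist.items())
        },
        "origin_composition_pct": {
            k: _pct(v, ins_reads) for k, v in sorted(origin_comp.items())
        },
        "mh_initiated_pct": _pct(mh_init_reads, templated_reads),
        "mh_ended_pct": _pct(mh_end_reads, templated_reads),
        "mh_initiated_and_ended_pct": _pct(mh_both_reads, templated_reads),
        "insertion_hotspots_pct": {
            k: _pct(v, total) for k, v in sorted(hotspots.items())
        },
        "origin_position_counts": {
            f"{name}:{strand}{start}": v
            for (name, strand, start), v in sorted(origin_positions.items())
        },
    }
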