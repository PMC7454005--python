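"""End-to-end junction analysis: reads -> events -> filtered, classified calls."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .constructs import AmpliconRef
from .pipeline import (
    REFERENCE,
    SOFT_CLIPPED,
    AlignConfig,
    AlignmentResult,
    EventGroup,
    MergedRead,
    RepairEvent,
    align_read,
    extract_events,
    group_events,
    realign_softclip,
)
from .scars import (
    TMEJ_WINDOW,
    DeletionCall,
    InsertionCall,
    NoiseModel,
    classify_deletions,
    classify_insertions,
    filter_noise,
    summarize_assay,
)


@dataclass
class JunctionAnalysis:
    read_classes: dict[str, str]
    read_events: dict[str, list[RepairEvent]]
    groups: list[EventGroup]
    retained: list[EventGroup]
    background: list[EventGroup]
    noise_model: NoiseModel | None
    deletion_calls: list[DeletionCall]
    insertion_calls: list[InsertionCall]
    summary: dict
    unaligned: list[str] = field(default_factory=list)

    @property
    def n_precise(self) -> int:
        return sum(1 for c in self.read_classes.values() if c == REFERENCE)

    def event_table(self) -> pd.DataFrame:
        rows = []
        for rid, events in self.read_events.items():
            cls = self.read_classes[rid]
            if not events:
                rows.append(
                    {
                        "read_id": rid,
                        "class": cls,
                        "kind": "",
                        "start": 0,
                        "end": 0,
                        "length": 0,
                        "sequence": "",
                    }
                )
            for ev in events:
                rows.append(
                    {
                        "read_id": rid,
                        "class": cls,
                        "kind": ev.kind,
                        "start": ev.start if ev.kind == "del" else ev.pos,
                        "end": ev.end if ev.kind == "del" else ev.pos,
                        "length": ev.length,
                        "sequence": ev.sequence,
                    }
                )
        return pd.DataFrame(
            rows, columns=["read_id", "class", "kind", "start", "end", "length", "sequence"]
        )


def analyze_junction_reads(
    reads: Sequence[MergedRead],
    amplicon: AmpliconRef,
    assay: str = "proximal",
    construct: tuple[str, str] | None = None,
    amplicon_offset: int = 0,
    extra_refs: Sequence[tuple[str, str]] = (),
    ci_level: float | None = None,
    background_lambda: float | None = None,
    tmej_window: tuple[int, int] = TMEJ_WINDOW,
    nearby_window: int = 100,
    length_bounds: tuple[int, int] = (5, 15),
    config: AlignConfig | None = None,
) -> JunctionAnalysis:
    """Run the full junction arm over merged reads.

    ``construct``/``amplicon_offset`` define the template search space for
    insertion-origin classification (defaults to the amplicon itself);
    ``ci_level`` of None disables Poisson noise filtering.
    """
    config = config or AlignConfig()
    primary = construct or (amplicon.name, amplicon.sequence)

    read_classes: dict[str, str] = {}
    read_events: dict[str, list[RepairEvent]] = {}
    unaligned: list[str] = []
    all_events: list[RepairEvent] = []
    for read in reads:
        aln: AlignmentResult | None = align_read(read, amplicon, config)
        if aln.low_score or aln.has_clip():
            aln = realign_softclip(read, amplicon, prior=aln, config=config)
        if aln is None:
            unaligned.append(read.id)
            continue
        cls, events = extract_events(aln)
        if aln.low_score:
            cls = SOFT_CLIPPED
        read_classes[read.id] = cls
        read_events[read.id] = events
        all_events.extend(events)

    groups = group_events(all_events)
    if ci_level is not None and groups:
        retained, background, model = filter_noise(
            groups, level=ci_level, lam=background_lambda
        )
    else:
        retained, background, model = list(groups), [], None

    deletion_calls = classify_deletions(
        (g for g in retained if g.kind == "del"), amplicon.sequence, tmej_window
    )
    insertion_calls = classify_insertions(
        (g for g in retained if g.kind == "ins"),
        primary,
        extra_refs,
        nearby_window=nearby_window,
        length_bounds=length_bounds,
        coord_offset=amplicon_offset,
    )
    n_precise = sum(1 for c in read_classes.values() if c == REFERENCE)
    summary = summarize_assay(n_precise, deletion_calls, insertion_calls, assay=assay)
    return JunctionAnalysis(
        read_classes=read_classes,
        read_events=read_events,
        groups=groups,
        retained=retained,
        background=background,
        noise_model=model,
        deletion_calls=deletion_calls,
        insertion_calls=insertion_calls,
        summary=summary,
        unaligned=unaligned,
    )
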