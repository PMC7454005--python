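"""Junction read simulator with planted repair outcomes and known truth.

Every planted event is self-verified before emission: planted deletions are
re-measured with the microhomology operation, planted insertions are classified
back through the origin classifier and MH-flag computation, and only events
that round-trip to the requested labels are emitted.  Reads carry substitution
errors at a configurable rate; spurious background event groups are injected
with Poisson-distributed supporting-read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import DNA, revcomp
from .constructs import AmpliconRef
from .pipeline import MergedRead
from .scars import (
    OriginHit,
    classify_insertion_origin,
    deletion_microhomology,
    insertion_mh_flags,
)


class PlantingError(ValueError):
    """Requested event geometry cannot be realized in the reference."""


@dataclass
class OutcomeSpec:
    """One component of the planted outcome mixture."""

    name: str
    kind: str  # precise | fill_in | deletion | insertion | random_insertion
    proportion: float
    length: int = 0
    mh: int = 0  # deletion junction MH
    origin_class: str = ""  # insertion: distant|nearby|snapback|direct_repeat
    mh_init: int | None = None  # None = unconstrained
    mh_end: int | None = None

    def __post_init__(self) -> None:
        kinds = ("precise", "fill_in", "deletion", "insertion", "random_insertion")
        if self.kind not in kinds:
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.proportion < 0:
            raise ValueError("proportions must be >= 0")


@dataclass
class JunctionSimSpec:
    amplicon: AmpliconRef
    cut_pos: int  # 1-based base immediately left of the break boundary
    outcomes: list[OutcomeSpec]
    depth: int = 1000
    error_rate: float = 0.0
    background_lambda: float = 0.0
    n_background_groups: int = 0
    # template search space: primary construct containing the amplicon
    construct: tuple[str, str] | None = None
    amplicon_offset: int = 0  # construct position of amplicon base 1, minus 1
    nearby_window: int = 100
    edge_margin: int = 30  # planted events keep this much intact at read ends

    def __post_init__(self) -> None:
        total = sum(o.proportion for o in self.outcomes)
        if not np.isclose(total, 1.0):
            raise ValueError(f"outcome proportions sum to {total}, expected 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.construct is None:
            self.construct = (self.amplicon.name, self.amplicon.sequence)


@dataclass
class SimTruth:
    """Per-read outcome labels plus the planted event parameters."""

    table: pd.DataFrame  # read_id, outcome, kind, start, end, pos, sequence, ...
    planted: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# planting


def plant_deletion(
    ref: str,
    length: int,
    target_mh: int,
    cut_pos: int,
    edge_margin: int = 30,
) -> tuple[int, int]:
    """Find a canonical (leftmost) deletion spanning the cut with the given MH.

    Returns 1-based (start, end); raises PlantingError when no placement with
    exactly ``target_mh`` exists near the cut.
    """
    n = len(ref)
    for start in range(
        max(edge_margin + 1, cut_pos - length - 60), min(cut_pos + 60, n - length) + 1
    ):
        end = start + length - 1
        if end > n - edge_margin:
            continue
        if not (start <= cut_pos + 1 and end >= cut_pos):
            continue  # must overlap the break boundary
        if start > 1 and ref[start - 2] == ref[end - 1]:
            continue  # not leftmost placement
        if deletion_microhomology(ref, start, end) == target_mh:
            return start, end
    raise PlantingError(
        f"no length-{length} deletion with MH {target_mh} found at the cut"
    )


def _requested_ok(value: int | None, computed_called: int) -> bool:
    return value is None or computed_called == value


def plant_insertion(
    spec: JunctionSimSpec,
    origin_class: str,
    length: int,
    mh_init: int | None = None,
    mh_end: int | None = None,
) -> tuple[str, OriginHit]:
    """Insertion sequence for the cut site that round-trips to the request.

    The returned event is verified against the origin classifier and MH-flag
    computation before being accepted.
    """
    amp = spec.amplicon.sequence
    name, construct = spec.construct
    jp = spec.cut_pos + spec.amplicon_offset  # junction in construct coords
    refs = {name: construct}
    left_base = amp[spec.cut_pos - 1]  # shift-left guard

    def verify(ins: str, origin: OriginHit) -> bool:
        if ins[-1] == left_base:
            return False  # would left-shift to a different canonical placement
        cls, candidates = classify_insertion_origin(
            ins, jp, (name, construct), nearby_window=spec.nearby_window
        )
        if cls != origin_class or len(candidates) != 1 or candidates[0] != origin:
            return False
        init, end_ = insertion_mh_flags(ins, jp, origin, refs, name)
        return _requested_ok(mh_init, init) and _requested_ok(mh_end, end_)

    candidates: list[tuple[str, OriginHit]] = []
    if origin_class == "direct_repeat":
        ins = construct[jp - length : jp]
        candidates.append((ins, OriginHit(name, "+", jp - length + 1, jp)))
        ins_r = construct[jp : jp + length]
        candidates.append((ins_r, OriginHit(name, "+", jp + 1, jp + length)))
    elif origin_class in ("nearby", "distant", "snapback"):
        strand = "-" if origin_class == "snapback" else "+"
        if origin_class == "nearby" or origin_class == "snapback":
            lo = max(1, jp - spec.nearby_window + 1)
            hi = min(len(construct) - length + 1, jp + spec.nearby_window)
        else:
            lo, hi = 1, len(construct) - length + 1
        for start in range(lo, hi + 1):
            seg = construct[start - 1 : start - 1 + length]
            ins = revcomp(seg) if strand == "-" else seg
            hit = OriginHit(name, strand, start, start + length - 1)
            if origin_class == "nearby" and (hit.end == jp or hit.start == jp + 1):
                continue  # that would be a direct repeat
            candidates.append((ins, hit))
    else:
        raise ValueError(f"cannot plant origin class {origin_class!r}")

    for ins, hit in candidates:
        if verify(ins, hit):
            return ins, hit
    raise PlantingError(
        f"no realizable {origin_class} insertion of length {length} "
        f"(mh_init={mh_init}, mh_end={mh_end})"
    )


def plant_random_insertion(
    spec: JunctionSimSpec, length: int, rng: np.random.Generator
) -> str:
    name, construct = spec.construct
    jp = spec.cut_pos + spec.amplicon_offset
    left_base = spec.amplicon.sequence[spec.cut_pos - 1]
    for _ in range(1000):
        ins = "".join(rng.choice(list(DNA), size=length))
        if ins[-1] == left_base:
            continue
        cls, _ = classify_insertion_origin(
            ins, jp, (name, construct), nearby_window=spec.nearby_window
        )
        if cls == "random":
            return ins
    raise PlantingError("could not draw a template-free random insertion")


# ---------------------------------------------------------------------------
# read synthesis


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alternatives = [b for b in DNA if b != arr[i]]
        arr[i] = alternatives[rng.integers(3)]
    return "".join(arr)


def _product_for_outcome(
    spec: JunctionSimSpec, outcome: OutcomeSpec, planted: dict
) -> tuple[str, dict]:
    amp = spec.amplicon.sequence
    cut = spec.cut_pos
    if outcome.kind == "precise":
        return amp, {"kind": "precise"}
    if outcome.kind == "fill_in":
        dup = amp[cut]  # base right of the boundary is duplicated
        product = amp[: cut + 1] + amp[cut:]
        # canonical (left-aligned) description of the duplication
        pos, seq = cut + 1, dup
        while pos > 0 and amp[pos - 1] == seq[-1]:
            seq = amp[pos - 1] + seq[:-1]
            pos -= 1
        return product, {"kind": "ins", "pos": pos, "sequence": seq}
    if outcome.kind == "deletion":
        start, end = planted["start"], planted["end"]
        return amp[: start - 1] + amp[end:], {"kind": "del", "start": start, "end": end}
    # insertion / random_insertion
    ins = planted["sequence"]
    product = amp[:cut] + ins + amp[cut:]
    return product, {"kind": "ins", "pos": cut, "sequence": ins}


def simulate_reads(
    spec: JunctionSimSpec, seed: int
) -> tuple[list[MergedRead], SimTruth]:
    """Emit reads for the planted outcome mixture; deterministic under seed."""
    rng = np.random.default_rng(seed)
    amp = spec.amplicon.sequence

    planted: dict[str, dict] = {}
    for o in spec.outcomes:
        if o.kind == "deletion":
            start, end = plant_deletion(
                amp, o.length, o.mh, spec.cut_pos, edge_margin=spec.edge_margin
            )
            planted[o.name] = {
                "start": start,
                "end": end,
                "mh": o.mh,
            }
        elif o.kind == "insertion":
            ins, hit = plant_insertion(
                spec, o.origin_class, o.length, o.mh_init, o.mh_end
            )
            planted[o.name] = {
                "sequence": ins,
                "origin": hit,
                "origin_class": o.origin_class,
                "mh_init": o.mh_init,
                "mh_end": o.mh_end,
            }
        elif o.kind == "random_insertion":
            planted[o.name] = {
                "sequence": plant_random_insertion(spec, o.length, rng),
                "origin_class": "random",
            }

    counts = rng.multinomial(spec.depth, [o.proportion for o in spec.outcomes])
    reads: list[MergedRead] = []
    rows: list[dict] = []
    idx = 0
    for o, n in zip(spec.outcomes, counts):
        product, desc = _product_for_outcome(spec, o, planted.get(o.name, {}))
        extra = planted.get(o.name, {})
        for _ in range(n):
            rid = f"r{idx:06d}"
            idx += 1
            reads.append(
                MergedRead(
                    id=rid,
                    sequence=_apply_errors(product, spec.error_rate, rng),
                    provenance="single",
                )
            )
            rows.append(
                {
                    "read_id": rid,
                    "outcome": o.name,
                    "kind": desc["kind"],
                    "start": desc.get("start", 0),
                    "end": desc.get("end", 0),
                    "pos": desc.get("pos", 0),
                    "sequence": desc.get("sequence", ""),
                    "origin_class": extra.get("origin_class", ""),
                    "mh_init": -1 if extra.get("mh_init") is None else extra["mh_init"],
                    "mh_end": -1 if extra.get("mh_end") is None else extra["mh_end"],
                }
            )

    # spurious background groups with Poisson-distributed support
    taken = {(r["kind"], r["start"], r["end"], r["pos"], r["sequence"]) for r in rows}
    made = 0
    attempts = 0
    while made < spec.n_background_groups and attempts < 10000:
        attempts += 1
        support = int(rng.poisson(spec.background_lambda))
        if support == 0:
            made += 1  # a zero-count group simply never materializes
            continue
        if rng.random() < 0.5:
            length = int(rng.integers(1, 4))
            start = int(rng.integers(spec.edge_margin, len(amp) - spec.edge_margin - length))
            end = start + length - 1
            while start > 1 and amp[start - 2] == amp[end - 1]:
                start -= 1
                end -= 1
            desc = {"kind": "del", "start": start, "end": end, "pos": 0, "sequence": ""}
            product = amp[: start - 1] + amp[end:]
        else:
            length = int(rng.integers(1, 4))
            ins = "".join(rng.choice(list(DNA), size=length))
            pos = int(rng.integers(spec.edge_margin, len(amp) - spec.edge_margin))
            while pos > 0 and amp[pos - 1] == ins[-1]:
                ins = amp[pos - 1] + ins[:-1]
                pos -= 1
            desc = {"kind": "ins", "start": 0, "end": 0, "pos": pos, "sequence": ins}
            product = amp[:pos] + ins + amp[pos:]
        key = (desc["kind"], desc["start"], desc["end"], desc["pos"], desc["sequence"])
        if key in taken:
            continue
        taken.add(key)
        made += 1
        for _ in range(support):
            rid = f"r{idx:06d}"
            idx += 1
            reads.append(MergedRead(id=rid, sequence=product, provenance="single"))
            rows.append(
                {
                    "read_id": rid,
                    "outcome": "background",
                    "kind": desc["kind"],
                    "start": desc["start"],
                    "end": desc["end"],
                    "pos": desc["pos"],
                    "sequence": desc["sequence"],
                    "origin_class": "",
                    "mh_init": -1,
                    "mh_end": -1,
                }
            )

    table = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "outcome",
            "kind",
            "start",
            "end",
            "pos",
            "sequence",
            "origin_class",
            "mh_init",
            "mh_end",
        ],
    )
    return reads, SimTruth(table=table, planted=planted)


def write_fastq(reads: Sequence[MergedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def reads_to_fastq_bytes(reads: Sequence[MergedRead]) -> bytes:
    chunks = []
    for r in reads:
        chunks.append(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return "".join(chunks).encode()


def preset_spec(
    assay: str,
    depth: int = 1000,
    error_rate: float = 0.0,
    background_lambda: float = 0.0,
    n_background_groups: int = 0,
) -> JunctionSimSpec:
    """Ready-made mixture specs for the two assay configurations.

    The proximal preset mimics the single-cut amplicon (about 90% precise
    joining, a staggered-end fill-in class, MH-stratified deletions); the
    distal preset mixes deletions of MH 0-4 with templated insertions of each
    origin class over the joined-junction amplicon, searching the full joined
    construct for templates.
    """
    from .constructs import (
        HPRT_CUT_RIGHT,
        distal_amplicon_reference,
        ej5_joined_reference,
        hprt_reference,
    )

    if assay == "proximal":
        amp = hprt_reference()
        outcomes = [
            OutcomeSpec("precise", "precise", 0.90),
            OutcomeSpec("fill_in", "fill_in", 0.04),
            OutcomeSpec("del_mh3", "deletion", 0.02, length=6, mh=3),
            OutcomeSpec("del_mh1", "deletion", 0.01, length=4, mh=1),
            OutcomeSpec("del_mh0", "deletion", 0.01, length=5, mh=0),
            OutcomeSpec("ins_random", "random_insertion", 0.02, length=8),
        ]
        return JunctionSimSpec(
            amplicon=amp,
            cut_pos=HPRT_CUT_RIGHT - 1,
            outcomes=outcomes,
            depth=depth,
            error_rate=error_rate,
            background_lambda=background_lambda,
            n_background_groups=n_background_groups,
        )
    if assay == "distal":
        amp = distal_amplicon_reference()
        joined = ej5_joined_reference()
        offset = joined.sequence.index(amp.sequence)
        _, cut_right = amp.feature("junction")
        outcomes = [
            OutcomeSpec("precise", "precise", 0.40),
            OutcomeSpec("del_mh0", "deletion", 0.08, length=6, mh=0),
            OutcomeSpec("del_mh2", "deletion", 0.07, length=8, mh=2),
            OutcomeSpec("del_mh3", "deletion", 0.06, length=8, mh=3),
            OutcomeSpec("del_mh4", "deletion", 0.06, length=9, mh=4),
            OutcomeSpec("fill_in", "fill_in", 0.05),
            OutcomeSpec(
                "ins_distant", "insertion", 0.07, length=12, origin_class="distant",
                mh_init=3, mh_end=3,
            ),
            OutcomeSpec(
                "ins_nearby", "insertion", 0.06, length=8, origin_class="nearby",
                mh_init=2, mh_end=0,
            ),
            OutcomeSpec(
                "ins_snapback", "insertion", 0.05, length=8, origin_class="snapback",
                mh_init=3, mh_end=0,
            ),
            OutcomeSpec(
                "ins_direct", "insertion", 0.05, length=6, origin_class="direct_repeat",
            ),
            OutcomeSpec("ins_random", "random_insertion", 0.05, length=10),
        ]
        return JunctionSimSpec(
            amplicon=amp,
            cut_pos=cut_right - 1,
            outcomes=outcomes,
            depth=depth,
            error_rate=error_rate,
            background_lambda=background_lambda,
            n_background_groups=n_background_groups,
            construct=(joined.name, joined.sequence),
            amplicon_offset=offset,
        )
    raise ValueError(f"unknown assay preset {assay!r}")


def evaluate_calls(calls: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Confusion table and per-class recall/precision for labeled reads.

    Both frames need ``read_id`` and ``label`` columns; the read-id sets must
    match exactly.
    """
    if truth.empty:
        raise ValueError("empty truth table")
    if set(calls["read_id"]) != set(truth["read_id"]):
        raise ValueError("call/truth read ids do not match")
    merged = truth.merge(calls, on="read_id", suffixes=("_true", "_called"))
    confusion = pd.crosstab(merged["label_true"], merged["label_called"])
    metrics = {}
    for cls in confusion.index:
        tp = confusion.loc[cls, cls] if cls in confusion.columns else 0
        fn = confusion.loc[cls].sum() - tp
        fp = (confusion[cls].sum() - tp) if cls in confusion.columns else 0
        metrics[cls] = {
            "recall": tp / (tp + fn) if tp + fn else np.nan,
            "precision": tp / (tp + fp) if tp + fp else np.nan,
        }
    return {"confusion": confusion, "metrics": pd.DataFrame(metrics).T}
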