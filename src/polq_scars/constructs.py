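"""Assay construct model: coordinates, motif search, in-silico PCR, cleavage.

All coordinates are 1-based inclusive.  The module also builds deterministic
synthetic stand-in references for the two assays (a 9406 bp distal-EJ reporter
construct with two I-SceI sites, and a 546 bp proximal-EJ amplicon with a
nuclease cut site) engineered so that every printed coordinate of the assay
design holds: first I-SceI motif at 1758, PCR products of 546/597/429 bp with
the published primer sequences, and a 1769 bp deletion on direct ligation of
the two distal cut ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._seq import is_unambiguous, random_dna, revcomp

ISCEI_MOTIF = "TAGGGATAACAGGGTAAT"
# Top-strand cut after motif base 9, bottom-strand cut after motif base 5:
# both fragments carry a 4-nt 3' overhang spanning motif bases 6-9 ("ATAA").
_TOP_CUT = 9
_OVERHANG = 4

HPRT_F = "TCTTACTGCTTGCTGAGGGC"
HPRT_R = "TAATTTTGCAAGGGGGCCCA"
DISTAL_F = "GTCCCAAATCTGGCGGAG"
DISTAL_R = "GTAGCGGCTGAAGCACTG"
DISTAL_F2 = "AGGAAGGAAATGGGCGGGGA"
DISTAL_R2 = "AACTTCAGGGTCAGCTTGCC"


@dataclass(frozen=True)
class JunctionCoord:
    """Break point between two adjacent reference positions.

    Rendered in "left:right" notation with the downstream position first, e.g.
    the boundary between positions 261 and 262 is written "262:261".
    """

    left_pos: int  # downstream base (right of the break)
    right_pos: int  # upstream base (left of the break)

    def __post_init__(self) -> None:
        if self.left_pos != self.right_pos + 1:
            raise ValueError("junction positions must be adjacent")

    def __str__(self) -> str:
        return f"{self.left_pos}:{self.right_pos}"

    @classmethod
    def from_string(cls, text: str) -> "JunctionCoord":
        left, right = (int(x) for x in text.split(":"))
        return cls(left_pos=left, right_pos=right)

    @classmethod
    def after(cls, pos: int) -> "JunctionCoord":
        """Junction immediately after 1-based position ``pos``."""
        return cls(left_pos=pos + 1, right_pos=pos)


@dataclass
class AmpliconRef:
    name: str
    sequence: str
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for label, start, end in self.features:
            if not 1 <= start <= end <= n:
                raise ValueError(f"feature {label} out of range: {start}..{end}")

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """1-based inclusive slice."""
        if not 1 <= start <= end <= len(self.sequence):
            raise ValueError(f"range {start}..{end} outside 1..{len(self.sequence)}")
        return self.sequence[start - 1 : end]

    def feature(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.features:
            if lab == label:
                return start, end
        raise KeyError(label)

    @classmethod
    def from_fasta(cls, path, name: str | None = None) -> "AmpliconRef":
        from Bio import SeqIO

        record = next(SeqIO.parse(str(path), "fasta"))
        return cls(name=name or record.id, sequence=str(record.seq))


@dataclass(frozen=True)
class MotifHit:
    start: int  # 1-based leftmost coordinate on the forward strand
    strand: str  # "+" | "-"


def find_motif(sequence: str, motif: str) -> list[MotifHit]:
    """All exact occurrences of ``motif`` on both strands, sorted by start."""
    sequence = sequence.upper()
    motif = motif.upper()
    if not is_unambiguous(motif):
        raise ValueError("motif must be unambiguous A/C/G/T")
    hits = []
    for strand, probe in (("+", motif), ("-", revcomp(motif))):
        if strand == "-" and probe == motif:
            continue  # palindromic: forward scan already reported it
        for m in re.finditer(f"(?={re.escape(probe)})", sequence):
            hits.append(MotifHit(start=m.start() + 1, strand=strand))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def in_silico_pcr(template: str, fwd_primer: str, rev_primer: str) -> str:
    """Product spanning the forward primer through revcomp of the reverse primer.

    Each primer must match the template exactly once in the productive
    orientation (forward primer on the top strand, reverse primer on the
    bottom strand, downstream of the forward primer).
    """
    template = template.upper()
    fwd = fwd_primer.upper()
    rev_rc = revcomp(rev_primer.upper())

    def occurrences(probe: str) -> list[int]:
        return [m.start() for m in re.finditer(f"(?={re.escape(probe)})", template)]

    fwd_hits = occurrences(fwd)
    rev_hits = occurrences(rev_rc)
    if len(fwd_hits) != 1:
        if not fwd_hits and occurrences(revcomp(fwd)):
            raise ValueError("forward primer matches only in inverted orientation")
        raise ValueError(f"forward primer matches {len(fwd_hits)} times, need exactly 1")
    if len(rev_hits) != 1:
        if not rev_hits and occurrences(rev_primer.upper()):
            raise ValueError("reverse primer matches only in inverted orientation")
        raise ValueError(f"reverse primer matches {len(rev_hits)} times, need exactly 1")
    start = fwd_hits[0]
    end = rev_hits[0] + len(rev_rc)
    if end <= start:
        raise ValueError("reverse primer site lies upstream of the forward primer")
    return template[start:end]


@dataclass
class CutEnds:
    """The two fragments of one I-SceI cut, each with a 4-nt 3' overhang."""

    site_start: int  # 1-based start of the 18 bp recognition motif
    upstream_top: str  # top strand of the upstream fragment (ends in overhang)
    downstream_top: str  # top strand of the downstream fragment
    overhang: str  # overhang bases as top-strand sequence

    @property
    def cut(self) -> JunctionCoord:
        return JunctionCoord.after(self.site_start + _TOP_CUT - 1)

    def religate(self) -> str:
        return self.upstream_top + self.downstream_top


def isce1_cut(sequence: str, site_start: int) -> CutEnds:
    """Cleave at the motif starting at 1-based ``site_start``."""
    sequence = sequence.upper()
    s = site_start
    if sequence[s - 1 : s - 1 + len(ISCEI_MOTIF)] != ISCEI_MOTIF:
        raise ValueError(f"I-SceI motif not present at position {s}")
    top_cut = s - 1 + _TOP_CUT  # python index of first base right of top cut
    return CutEnds(
        site_start=s,
        upstream_top=sequence[:top_cut],
        downstream_top=sequence[top_cut:],
        overhang=sequence[top_cut - _OVERHANG : top_cut],
    )


def simple_join(
    upstream: CutEnds, downstream: CutEnds, intact_length: int
) -> tuple[str, int]:
    """Ligate the upstream fragment of one cut to the downstream of another.

    Returns the joined top-strand sequence and the deletion length relative to
    an intact reference of ``intact_length``.
    """
    if upstream.overhang != downstream.overhang:
        raise ValueError(
            f"incompatible overhangs: {upstream.overhang} vs {downstream.overhang}"
        )
    joined = upstream.upstream_top + downstream.downstream_top
    return joined, intact_length - len(joined)


# ---------------------------------------------------------------------------
# deterministic stand-in references

_EJ5_LENGTH = 9406
_EJ5_SEED = 94061758
_SITE_A = 1758
_SITE_B = 3527  # SITE_A + 1769: direct ligation deletes siteB - siteA bases
_HPRT_LENGTH = 546
_HPRT_SEED = 546273
HPRT_CUT_RIGHT = 274  # staggered nuclease cut boundary 273|274


def _stamp(seq: list[str], start: int, insert: str) -> None:
    seq[start - 1 : start - 1 + len(insert)] = list(insert)


def _assert_counts(seq: str, expected: dict[str, int]) -> None:
    for probe, count in expected.items():
        found = len(find_motif(seq, probe))
        if found != count:
            raise AssertionError(
                f"construct self-check failed: {probe[:12]}... occurs {found}x, "
                f"expected {count}"
            )


def ej5_reference() -> AmpliconRef:
    """Synthetic 9406 bp distal-EJ reporter with two I-SceI sites.

    Deterministic stand-in for the reporter construct: motif starts at 1758
    and 3527, primer sites placed so the first-round and nested in-silico PCR
    products on the joined allele are 597 and 429 bp.
    """
    rng = np.random.default_rng(_EJ5_SEED)
    seq = list(random_dna(rng, _EJ5_LENGTH))
    _stamp(seq, 1422, DISTAL_F)
    _stamp(seq, 1506, DISTAL_F2)
    _stamp(seq, _SITE_A, ISCEI_MOTIF)
    _stamp(seq, _SITE_B, ISCEI_MOTIF)
    _stamp(seq, 3684, revcomp(DISTAL_R2))
    _stamp(seq, 3770, revcomp(DISTAL_R))
    text = "".join(seq)
    _assert_counts(
        text,
        {
            ISCEI_MOTIF: 2,
            DISTAL_F: 1,
            DISTAL_F2: 1,
            DISTAL_R: 1,
            DISTAL_R2: 1,
        },
    )
    return AmpliconRef(
        name="EJ5_reporter",
        sequence=text,
        features=[
            ("distal_F", 1422, 1439),
            ("distal_F2", 1506, 1525),
            ("isce1_site_1", _SITE_A, _SITE_A + 17),
            ("isce1_site_2", _SITE_B, _SITE_B + 17),
            ("distal_R2_rc", 3684, 3703),
            ("distal_R_rc", 3770, 3787),
        ],
    )


def ej5_joined_reference() -> AmpliconRef:
    """Simple-join product of cutting both sites and ligating the distal ends."""
    ej5 = ej5_reference()
    cut_a = isce1_cut(ej5.sequence, _SITE_A)
    cut_b = isce1_cut(ej5.sequence, _SITE_B)
    joined, deletion = simple_join(cut_a, cut_b, len(ej5))
    ref = AmpliconRef(
        name="EJ5_joined",
        sequence=joined,
        features=[
            ("isce1_site", _SITE_A, _SITE_A + 17),
            ("junction", cut_a.cut.right_pos, cut_a.cut.left_pos),
        ],
    )
    assert deletion == _SITE_B - _SITE_A
    return ref


def distal_amplicon_reference() -> AmpliconRef:
    """429 bp nested PCR product over the joined junction.

    The reconstituted I-SceI site spans amplicon positions 253-270 and the
    original cut boundary is 262:261 in junction notation.
    """
    joined = ej5_joined_reference()
    product = in_silico_pcr(joined.sequence, DISTAL_F2, DISTAL_R2)
    offset = joined.sequence.index(DISTAL_F2)  # 0-based start of amplicon in joined
    site_start = _SITE_A - offset
    cut = JunctionCoord.after(_SITE_A + _TOP_CUT - 1 - offset)
    return AmpliconRef(
        name="distal_amplicon",
        sequence=product,
        features=[
            ("isce1_site", site_start, site_start + 17),
            ("junction", cut.right_pos, cut.left_pos),
        ],
    )


def hprt_reference() -> AmpliconRef:
    """Synthetic 546 bp proximal-EJ amplicon with a staggered nuclease cut.

    The cut boundary is 273|274 and the 5'-protruding base at 274 is a T, so
    fill-in joining duplicates a single T.
    """
    rng = np.random.default_rng(_HPRT_SEED)
    seq = list(random_dna(rng, _HPRT_LENGTH))
    _stamp(seq, 1, HPRT_F)
    _stamp(seq, _HPRT_LENGTH - len(HPRT_R) + 1, revcomp(HPRT_R))
    seq[HPRT_CUT_RIGHT - 1] = "T"
    text = "".join(seq)
    _assert_counts(text, {HPRT_F: 1, HPRT_R: 1})
    return AmpliconRef(
        name="HPRT_amplicon",
        sequence=text,
        features=[
            ("hprt_F", 1, 20),
            ("hprt_R_rc", _HPRT_LENGTH - 19, _HPRT_LENGTH),
            ("cut", HPRT_CUT_RIGHT - 1, HPRT_CUT_RIGHT),
        ],
    )
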