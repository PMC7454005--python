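"""SBS96 and ID83 mutation-channel catalogs.

Single-base substitutions are classified into the 96 trinucleotide-context
channels (6 pyrimidine-centered substitution types x 4 five-prime x 4
three-prime flanking bases).  Small insertions/deletions are classified into
the 83 indel channels, partitioned 12 + 12 + 24 + 24 + 11:

* 12 one-bp deletions: C/T deleted base x homopolymer length 1..5, 6+
* 12 one-bp insertions: C/T inserted base x homopolymer length 0..4, 5+
* 24 >=2 bp deletions: length 2,3,4,5+ x number of additional repeat copies
  0..4, 5+
* 24 >=2 bp insertions: same layout
* 11 >=2 bp deletions at microhomologies: (length, MH length) with
  1 <= MH < length, lengths capped at 5+ and MH at 5+

Channel labels follow the COSMIC/PCAWG style, e.g. ``A[C>T]G``, ``1:Del:C:0``,
``5:Del:M:5``.  Deletion microhomology is measured by placement enumeration
(see :mod:`polq_scars._mh`); precedence is repeat > microhomology > plain.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from ._mh import placement_mh
from ._seq import comp, is_unambiguous, revcomp

SBS_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
PYRIMIDINES = "CT"
PURINES = "AG"


class WindowTooShortError(ValueError):
    """Reference window does not allow an unambiguous context bin."""


class NotPureIndelError(ValueError):
    """Ref/alt alleles do not reduce to a pure insertion or deletion."""


@dataclass(frozen=True)
class SbsChannel:
    pyrimidine_ref: str
    alt: str
    five_prime: str
    three_prime: str

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.pyrimidine_ref}>{self.alt}]{self.three_prime}"


@dataclass(frozen=True)
class IdChannel:
    kind: str  # "del" | "ins"
    size_class: int  # 1..5 (5 means 5+)
    context: str  # "hp" (homopolymer), "rep" (repeat units), "mh"
    context_bin: int
    base: str = ""  # pyrimidine-normalized base, 1 bp channels only

    @property
    def label(self) -> str:
        mid = "Del" if self.kind == "del" else "Ins"
        if self.size_class == 1:
            return f"1:{mid}:{self.base}:{self.context_bin}"
        code = "M" if self.context == "mh" else "R"
        return f"{self.size_class}:{mid}:{code}:{self.context_bin}"

    @classmethod
    def from_label(cls, label: str) -> "IdChannel":
        size, mid, code, n = label.split(":")
        kind = "del" if mid == "Del" else "ins"
        if size == "1":
            return cls(kind=kind, size_class=1, context="hp", context_bin=int(n), base=code)
        context = "mh" if code == "M" else "rep"
        return cls(kind=kind, size_class=int(size), context=context, context_bin=int(n))


def _sbs_labels() -> list[str]:
    return [
        f"{five}[{sub}]{three}"
        for sub in SBS_SUBSTITUTIONS
        for five in "ACGT"
        for three in "ACGT"
    ]


def _id_labels() -> list[str]:
    labels: list[str] = []
    labels += [f"1:Del:{b}:{i}" for b in "CT" for i in range(6)]
    labels += [f"1:Ins:{b}:{i}" for b in "CT" for i in range(6)]
    labels += [f"{n}:Del:R:{i}" for n in range(2, 6) for i in range(6)]
    labels += [f"{n}:Ins:R:{i}" for n in range(2, 6) for i in range(6)]
    labels += ["2:Del:M:1"]
    labels += [f"3:Del:M:{i}" for i in (1, 2)]
    labels += [f"4:Del:M:{i}" for i in (1, 2, 3)]
    labels += [f"5:Del:M:{i}" for i in (1, 2, 3, 4, 5)]
    return labels


_SBS_LABELS = _sbs_labels()
_ID_LABELS = _id_labels()


def enumerate_channels(kind: str) -> list[str]:
    """Return the ordered channel label list for ``kind`` ("sbs" or "id")."""
    if kind == "sbs":
        return list(_SBS_LABELS)
    if kind == "id":
        return list(_ID_LABELS)
    raise ValueError(f"unknown channel kind: {kind!r}")


def mh_deletion_labels() -> list[str]:
    """The 11 microhomology-deletion labels within the ID83 catalog."""
    return [lab for lab in _ID_LABELS if ":Del:M:" in lab]


def classify_sbs(triplet: str, alt: str) -> str:
    """Classify an SNV given its 3-base reference context and alternate base.

    Purine-centered contexts are folded through the reverse complement so the
    reported channel is always pyrimidine-centered.
    """
    triplet = triplet.upper()
    alt = alt.upper()
    if len(triplet) != 3 or not is_unambiguous(triplet):
        raise ValueError(f"triplet must be 3 unambiguous bases, got {triplet!r}")
    if len(alt) != 1 or not is_unambiguous(alt):
        raise ValueError(f"alt must be one unambiguous base, got {alt!r}")
    if alt == triplet[1]:
        raise ValueError("alt equals the reference base")
    if triplet[1] in PURINES:
        triplet = revcomp(triplet)
        alt = comp(alt)
    return f"{triplet[0]}[{triplet[1]}>{alt}]{triplet[2]}"


def _strip_alleles(ref_allele: str, alt_allele: str) -> tuple[int, str, str]:
    """Remove the common prefix then common suffix; return (prefix_len, ref, alt)."""
    k = 0
    while k < len(ref_allele) and k < len(alt_allele) and ref_allele[k] == alt_allele[k]:
        k += 1
    r, a = ref_allele[k:], alt_allele[k:]
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    return k, r, a


def _count_right_copies(window: str, start0: int, unit: str, cap: int) -> int:
    """Count adjacent full copies of ``unit`` starting at 0-based ``start0``.

    Raises WindowTooShortError if counting is cut off by the window boundary
    before the cap is reached.
    """
    n = 0
    L = len(unit)
    while n < cap:
        lo = start0 + n * L
        if lo + L > len(window):
            raise WindowTooShortError("window too short to resolve repeat bin")
        if window[lo : lo + L] != unit:
            break
        n += 1
    return n


def classify_indel(window: str, pos: int, ref_allele: str, alt_allele: str) -> str:
    """Classify a pure indel into its ID83 channel.

    ``window`` is the reference sequence around the site and ``pos`` the
    1-based position of the first base of ``ref_allele`` within it.  Alleles
    may be given VCF-style (shared anchor base) or bare; they are reduced to a
    pure event and left-aligned before binning.
    """
    window = window.upper()
    ref_allele = ref_allele.upper()
    alt_allele = alt_allele.upper()
    if not is_unambiguous(window):
        raise ValueError("window contains ambiguous bases")
    for allele in (ref_allele, alt_allele):
        if allele and not is_unambiguous(allele):
            raise ValueError(f"allele contains ambiguous bases: {allele!r}")

    k, r, a = _strip_alleles(ref_allele, alt_allele)
    if (len(r) == 0) == (len(a) == 0):
        raise NotPureIndelError(f"not a pure indel: {ref_allele}>{alt_allele}")

    if r:  # deletion of r at window positions (pos+k)..(pos+k+len(r)-1)
        L = len(r)
        s = pos + k  # 1-based start of deleted segment
        if s < 1 or s + L - 1 > len(window):
            raise ValueError("deletion coordinates outside window")
        if window[s - 1 : s - 1 + L] != r:
            raise ValueError("ref allele does not match window")
        while s > 1 and window[s - 2] == window[s - 2 + L]:
            s -= 1
        return _classify_deletion(window, s, L)

    # insertion of a after window position (pos + k - 1)
    ins = a
    p = pos + k - 1  # 1-based base to the left of the insertion (0 = start)
    if p < 0 or p > len(window):
        raise ValueError("insertion position outside window")
    while p > 0 and window[p - 1] == ins[-1]:
        ins = window[p - 1] + ins[:-1]
        p -= 1
    return _classify_insertion(window, p, ins)


def _classify_deletion(window: str, s: int, L: int) -> str:
    e = s + L - 1
    if L == 1:
        b = window[s - 1]
        run = 1
        i = s - 2
        while i >= 0 and window[i] == b and run < 6:
            run += 1
            i -= 1
        j = e  # 0-based index just right of the deleted base
        while j < len(window) and window[j] == b and run < 6:
            run += 1
            j += 1
        # truncated by a window edge before the bin was decided -> ambiguous
        if run < 6 and (i < 0 or j >= len(window)):
            raise WindowTooShortError("window too short to resolve homopolymer bin")
        if b in PURINES:
            b = comp(b)
        return f"1:Del:{b}:{min(run, 6) - 1}"
    deleted = window[s - 1 : e]
    copies = _count_right_copies(window, e, deleted, cap=5)
    size = min(L, 5)
    if copies >= 1:
        return f"{size}:Del:R:{min(copies, 5)}"
    mh = placement_mh(window, s, e)
    if mh >= 1:
        return f"{size}:Del:M:{min(mh, L - 1, 5)}"
    return f"{size}:Del:R:0"


def _classify_insertion(window: str, p: int, ins: str) -> str:
    L = len(ins)
    if L == 1:
        b = ins
        run = 0
        j = p  # 0-based index of the base right of the insertion point
        while j < len(window) and window[j] == b and run < 5:
            run += 1
            j += 1
        if run < 5 and j >= len(window):
            raise WindowTooShortError("window too short to resolve homopolymer bin")
        if b in PURINES:
            b = comp(b)
        return f"1:Ins:{b}:{min(run, 5)}"
    copies = _count_right_copies(window, p, ins, cap=5)
    return f"{min(L, 5)}:Ins:R:{min(copies, 5)}"


# ---------------------------------------------------------------------------
# catalogs


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    consequence: str = "other"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")


@dataclass
class MutationCatalog:
    sample_id: str
    sbs_counts: dict[str, int] = field(default_factory=dict)
    id_counts: dict[str, int] = field(default_factory=dict)
    unclassified: list[tuple[VariantRecord, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lab in _SBS_LABELS:
            self.sbs_counts.setdefault(lab, 0)
        for lab in _ID_LABELS:
            self.id_counts.setdefault(lab, 0)

    @property
    def n_sbs(self) -> int:
        return sum(self.sbs_counts.values())

    @property
    def n_id(self) -> int:
        return sum(self.id_counts.values())

    def to_frame(self):
        import pandas as pd

        rows = [("sbs", lab, self.sbs_counts[lab]) for lab in _SBS_LABELS]
        rows += [("id", lab, self.id_counts[lab]) for lab in _ID_LABELS]
        return pd.DataFrame(rows, columns=["kind", "channel", "count"])


def _chrom_getter(reference) -> Callable[[str], str]:
    if callable(reference):
        return lambda c: str(reference(c)).upper()
    if isinstance(reference, Mapping) or hasattr(reference, "__getitem__"):
        return lambda c: str(reference[c]).upper()
    raise TypeError("reference accessor must be callable or mapping-like")


_WINDOW_PAD = 80


def build_catalog(
    variants: Iterable[VariantRecord],
    reference,
    sample_id: str = "sample",
) -> MutationCatalog:
    """Aggregate per-sample SBS96/ID83 channel counts.

    Unclassifiable variants (ambiguous bases, MNVs, window limits) are
    collected on the returned catalog rather than silently dropped.  A missing
    chromosome or reference/allele mismatch raises.
    """
    get = _chrom_getter(reference)
    cat = MutationCatalog(sample_id=sample_id)
    sbs = Counter()
    idc = Counter()
    for v in variants:
        ref_a, alt_a = v.ref_allele.upper(), v.alt_allele.upper()
        try:
            seq = get(v.chrom)
        except Exception as exc:  # noqa: BLE001 - surfaced as lookup failure
            raise KeyError(f"reference lookup failed for {v.chrom!r}: {exc}") from exc
        if not (is_unambiguous(ref_a) and is_unambiguous(alt_a)):
            cat.unclassified.append((v, "ambiguous bases"))
            continue
        if len(ref_a) == 1 and len(alt_a) == 1:
            if v.pos < 2 or v.pos > len(seq) - 1:
                cat.unclassified.append((v, "no flanking context"))
                continue
            triplet = seq[v.pos - 2 : v.pos + 1]
            if triplet[1] != ref_a:
                raise ValueError(
                    f"reference mismatch at {v.chrom}:{v.pos}: {triplet[1]} != {ref_a}"
                )
            if not is_unambiguous(triplet):
                cat.unclassified.append((v, "ambiguous context"))
                continue
            sbs[classify_sbs(triplet, alt_a)] += 1
            continue
        _, r, a = _strip_alleles(ref_a, alt_a)
        if (len(r) == 0) == (len(a) == 0):
            cat.unclassified.append((v, "not a pure indel"))
            continue
        lo = max(1, v.pos - _WINDOW_PAD)
        hi = min(len(seq), v.pos + len(ref_a) + _WINDOW_PAD)
        window = seq[lo - 1 : hi]
        try:
            idc[classify_indel(window, v.pos - lo + 1, ref_a, alt_a)] += 1
        except WindowTooShortError:
            cat.unclassified.append((v, "window too short"))
        except ValueError as exc:
            raise ValueError(f"variant {v.chrom}:{v.pos}: {exc}") from exc
    for lab, n in sbs.items():
        cat.sbs_counts[lab] = n
    for lab, n in idc.items():
        cat.id_counts[lab] = n
    return cat
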