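"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"


def comp(base: str) -> str:
    return base.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def is_unambiguous(seq: str) -> bool:
    return len(seq) > 0 and all(c in "ACGT" for c in seq.upper())


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n))
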