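"""Nucleotide-string helpers shared across modules.

Everything here works on plain upper-case strings; coordinates are 0-based
half-open unless a function says otherwise.
"""
from __future__ import annotations

import re

import numpy as np

#: IUPAC ambiguity codes mapped to the set of concrete bases they admit.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_iupac(seq: str) -> bool:
    return bool(seq) and all(c in IUPAC for c in seq)


def matches(base: str, code: str) -> bool:
    """True if a concrete base satisfies an IUPAC code."""
    return base in IUPAC[code]


def iupac_regex(site: str) -> re.Pattern:
    """Compile an overlapping-match regex for an IUPAC recognition site."""
    body = "".join(c if len(IUPAC[c]) == 1 else "[%s]" % IUPAC[c] for c in site)
    return re.compile("(?=%s)" % body)


def find_sites(seq: str, site: str) -> list[int]:
    """All (possibly overlapping) start positions of an IUPAC site in seq."""
    return [m.start() for m in iupac_regex(site).finditer(seq)]


def base_indices(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; any other character (e.g. N) maps to -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. random sequence with expected G+C fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(BASES), size=length, p=p))
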