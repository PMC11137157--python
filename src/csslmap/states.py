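"""Parental-origin call alphabet shared across the package.

A CSSL genotype at any point of the genome is one of four diploid states:
homozygous recurrent parent (REC), homozygous donor (DON), heterozygous
(HET), or unobserved (MISSING).  Window/marker classification adds a fifth
UNKNOWN state for positions the sliding-window rule cannot call.

Calls are stored as small integers (int8 arrays); the text serialization
uses the graphical-genotype convention A/B/H/- with A = recurrent parent.
"""

from __future__ import annotations

import numpy as np

REC: int = 0
DON: int = 1
HET: int = 2
MISSING: int = 3
UNKNOWN: int = 4

#: internal code -> TSV symbol (A = recurrent, B = donor)
SYMBOL = {REC: "A", DON: "B", HET: "H", MISSING: "-", UNKNOWN: "U"}
#: TSV symbol -> internal code
CODE = {v: k for k, v in SYMBOL.items()}

STATE_NAME = {REC: "REC", DON: "DON", HET: "HET", MISSING: "MISSING", UNKNOWN: "UNKNOWN"}
NAME_STATE = {v: k for k, v in STATE_NAME.items()}


def to_symbols(calls: np.ndarray) -> np.ndarray:
    """Map an int8 call array to the A/B/H/- symbol array."""
    lut = np.array([SYMBOL[i] for i in range(5)], dtype="U1")
    return lut[calls]


def from_symbols(symbols) -> np.ndarray:
    """Map A/B/H/- symbols (array-like of str) to int8 codes.

    Raises ``ValueError`` naming the first offending symbol.
    """
    arr = np.asarray(symbols, dtype="U1")
    out = np.empty(arr.shape, dtype=np.int8)
    flat_in, flat_out = arr.ravel(), out.ravel()
    for i, s in enumerate(flat_in):
        try:
            flat_out[i] = CODE[s]
        except KeyError:
            raise ValueError(f"unknown call symbol {s!r} at flat index {i}") from None
    return out
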