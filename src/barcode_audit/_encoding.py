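"""Internal nucleotide encoding shared by distance, audit and simulation code.

Bases are encoded as uint8: A=0, C=1, G=2, T=3.  With this coding A/G are
even and C/T odd, so two differing codes are a transition iff they have the
same parity and the transition partner of ``c`` is ``c ^ 2``.  Everything
else (IUPAC ambiguity codes, N, gaps, uncovered frame positions) maps to
``MISSING`` and is invisible to pairwise-deletion comparisons.
"""

from __future__ import annotations

import numpy as np

BARCODE_FRAME_LENGTH = 658

MISSING: int = 255

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = np.array(list("ACGT"), dtype="U1")

IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
ALLOWED_CHARS = set("ACGT") | IUPAC_AMBIGUOUS | {"-"}

_LUT = np.full(256, MISSING, dtype=np.uint8)
for _b, _c in _CODE.items():
    _LUT[ord(_b)] = _c


def encode(bases: str) -> np.ndarray:
    """Encode an upper-case nucleotide string; non-ACGT becomes MISSING."""
    raw = np.frombuffer(bases.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    """Decode an array of ACGT codes (no MISSING allowed) to a string."""
    if np.any(codes >= 4):
        raise ValueError("cannot decode MISSING/ambiguous codes")
    return "".join(_DECODE[codes])


def frame_array(bases: str, start: int, frame_length: int = BARCODE_FRAME_LENGTH) -> np.ndarray:
    """Place a sequence on the fixed barcode coordinate frame.

    Returns a ``frame_length`` uint8 array where positions not covered by
    the sequence, and covered positions holding ambiguity codes or gaps,
    are MISSING.  ``start`` is 1-based.
    """
    out = np.full(frame_length, MISSING, dtype=np.uint8)
    codes = encode(bases)
    stop = start - 1 + len(codes)
    if start < 1 or stop > frame_length:
        raise ValueError(
            f"sequence spans {start}..{stop}, outside the 1..{frame_length} frame"
        )
    out[start - 1 : stop] = codes
    return out
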