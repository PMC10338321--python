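"""The 21-character amino-acid alphabet (20 standard residues + gap).

All scoring in this package treats the gap as a first-class character, so
columns are always distributions over 21 symbols.  Sequences are stored as
strings but encoded to small integer arrays for numerical work; the gap is
always the last code (index 20).
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
ALPHABET: str = AMINO_ACIDS + GAP
ALPHABET_SIZE: int = len(ALPHABET)  # 21
GAP_CODE: int = ALPHABET_SIZE - 1

_CODE = {c: i for i, c in enumerate(ALPHABET)}


def is_valid_char(c: str) -> bool:
    return c in _CODE


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence string to uint8 codes (gap == 20)."""
    try:
        return np.fromiter((_CODE[c] for c in seq), dtype=np.uint8, count=len(seq))
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"illegal character {exc.args[0]!r} in sequence") from None


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)
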