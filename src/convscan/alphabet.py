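"""Amino-acid alphabet and residue encoding.

States are indexed alphabetically by one-letter code so that ``argmax`` over a
posterior vector breaks exact ties alphabetically, matching the reconstruction
tie-break rule used throughout the package.
"""

from __future__ import annotations

import numpy as np

#: Canonical residues, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Number of residue states.
N_STATES: int = 20

#: Integer code for a missing observation (gap or unknown).
MISSING: int = 20

#: The character written for a missing residue.
GAP_CODE: str = "-"

_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_GAP_CHARS = frozenset("-.?")


def encode_residue(ch: str) -> int:
    """Map a one-letter residue code to its state index.

    Gap characters (``-``, ``.``, ``?``) and ``X`` map to :data:`MISSING`.
    Any other letter is treated as unknown and also maps to :data:`MISSING`;
    callers that need to warn about non-standard letters should check
    membership in :data:`AMINO_ACIDS` first.
    """
    c = ch.upper()
    if c in _INDEX:
        return _INDEX[c]
    return MISSING


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a residue string as an int8 state vector."""
    return np.fromiter((encode_residue(c) for c in seq), dtype=np.int8, count=len(seq))


def decode_state(state: int) -> str:
    """Map a state index back to its one-letter code (``-`` for missing)."""
    if state == MISSING:
        return GAP_CODE
    return AMINO_ACIDS[state]


def decode_states(states: np.ndarray) -> str:
    """Decode an int state vector to a residue string."""
    return "".join(decode_state(int(s)) for s in states)
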