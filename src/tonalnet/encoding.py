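"""Fixed-width network codes for melodies and keys.

A melody is coded positionally: the input vector is a concatenation of 186
twelve-unit blocks, one per serial position, and position ``p`` carries a
single 1 at the chroma sounded there. Positions beyond the melody's length
stay all-zero, so absent tones contribute nothing to the first affine layer.
The teacher signal is a 24-bit one-hot code of the key (major keys 0-11 by
tonic, minor keys 12-23).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .corpus import KeyLabel, Melody

N_CHROMAS = 12
MAX_POSITIONS = 186
INPUT_SIZE = MAX_POSITIONS * N_CHROMAS  # 2232
N_KEYS = 24


class CapacityError(ValueError):
    """Melody exceeds the network's 186-position input capacity."""


def _as_chromas(melody: Melody | Sequence[int]) -> np.ndarray:
    chromas = np.asarray(
        melody.chromas if isinstance(melody, Melody) else list(melody), dtype=np.int64
    )
    if chromas.size == 0:
        raise ValueError("cannot encode an empty melody")
    if chromas.size > MAX_POSITIONS:
        raise CapacityError(
            f"melody has {chromas.size} tones; the input layer holds at most {MAX_POSITIONS}"
        )
    if np.any((chromas < 0) | (chromas > 11)):
        raise ValueError("chromas must be pitch classes 0..11")
    return chromas


def active_indices(melody: Melody | Sequence[int]) -> np.ndarray:
    """Flat indices of the 1-entries of :func:`encode_melody` (one per tone)."""
    chromas = _as_chromas(melody)
    return (np.arange(chromas.size) * N_CHROMAS + chromas).astype(np.int64)


def encode_melody(melody: Melody | Sequence[int]) -> np.ndarray:
    """Positional one-hot code: shape ``(2232,)``, one 1 per sounded tone."""
    vec = np.zeros(INPUT_SIZE)
    vec[active_indices(melody)] = 1.0
    return vec


def encode_key(key: KeyLabel) -> np.ndarray:
    """24-bit one-hot teacher signal with the 1 at ``key.index``."""
    bits = np.zeros(N_KEYS)
    bits[key.index] = 1.0
    return bits


def decode_key(index: int) -> KeyLabel:
    """Inverse of the output-unit numbering (0-11 major, 12-23 minor)."""
    if not 0 <= int(index) <= 23:
        raise ValueError(f"key index must be 0..23, got {index}")
    return KeyLabel.from_index(int(index))
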