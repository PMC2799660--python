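"""Genome sequences and position weight matrices.

A :class:`GenomeSequence` is a plain mapping from chromosome name to an
uppercase string over the alphabet ``{A, C, G, T, N}``.  A
:class:`PwmRecord` holds per-position base probabilities for a motif, with
columns in A, C, G, T order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: maps ASCII byte -> base code 0..3, N -> 4, anything else -> 5
_CODE_TABLE = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i
_CODE_TABLE[ord("N")] = 4


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    codes = _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() > 4:
        bad = seq[int(np.argmax(codes > 4))]
        raise FormatError(f"invalid base {bad!r} in sequence")
    return codes


@dataclass
class GenomeSequence:
    """Chromosome name -> uppercase sequence string over {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences


@dataclass
class PwmRecord:
    """A motif's position probability matrix.

    ``matrix`` has one row per motif position and four columns (A, C, G, T);
    every row sums to one.
    """

    tf_name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError("PWM matrix must have shape (n_positions, 4)")
        if self.matrix.shape[0] < 4:
            raise FormatError("PWM must have at least 4 positions")
        if (self.matrix < 0).any():
            raise FormatError("PWM probabilities must be non-negative")
        sums = self.matrix.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > 1e-9:
            raise FormatError("every PWM row must sum to 1 (tolerance 1e-9)")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        """Highest-probability base at each position (ties: first of ACGT)."""
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))
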