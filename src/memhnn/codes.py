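"""32-bit binary feature codes driving the pre-neurons.

A :class:`FeatureCode` is the interface between the EEG front-end and the
crossbar: an ordered vector of 32 bits (one per pre-neuron), optionally
carrying the vowel class label ``'a'``, ``'i'`` or ``'u'``.  Codes serialise
as one line of text each — a 32-character bitstring followed by the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

CLASSES = ("a", "i", "u")
N_BITS = 32


@dataclass(frozen=True)
class FeatureCode:
    """One binary feature pattern (default length 32) with an optional class label."""

    bits: tuple
    label: Optional[str] = None

    def __post_init__(self):
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError("feature code bits must be 0/1")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=float)

    @property
    def bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_bitstring(cls, s: str, label: Optional[str] = None) -> "FeatureCode":
        return cls(bits=tuple(int(c) for c in s.strip()), label=label)

    def hamming(self, other: "FeatureCode") -> int:
        if len(self) != len(other):
            raise ValueError("length mismatch")
        return int(sum(a != b for a, b in zip(self.bits, other.bits)))


def write_codes(path: str | Path, codes: Iterable[FeatureCode]) -> None:
    """Write codes as ``<bitstring> <label>`` lines (``-`` for unlabelled)."""
    lines = [f"{c.bitstring} {c.label or '-'}" for c in codes]
    Path(path).write_text("\n".join(lines) + "\n")


def read_codes(path: str | Path) -> List[FeatureCode]:
    codes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        label = None if len(parts) < 2 or parts[1] == "-" else parts[1]
        codes.append(FeatureCode.from_bitstring(parts[0], label=label))
    return codes


def codes_matrix(codes: Sequence[FeatureCode]) -> np.ndarray:
    """Stack codes into an (n_codes, n_bits) float matrix."""
    return np.stack([c.array for c in codes])
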