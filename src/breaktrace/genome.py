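"""In-memory reference genome with FASTA round-tripping.

Sequences are stored as uint8 code arrays (A=0, C=1, G=2, T=3, N=4) so
the simulator and the toy aligner can share cheap numpy operations.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .hotspots import SequenceSource

__all__ = ["Genome", "encode", "decode", "revcomp_codes"]

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i
_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


class Genome(SequenceSource):
    def __init__(self, arrays: Mapping[str, np.ndarray]) -> None:
        self._chroms: dict[str, np.ndarray] = {
            name: np.asarray(arr, dtype=np.uint8) for name, arr in arrays.items()
        }

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "Genome":
        return cls({name: encode(seq) for name, seq in sequences.items()})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        arrays: dict[str, np.ndarray] = {}
        name = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if name is not None:
                        arrays[name] = encode("".join(chunks))
                    name = line[1:].split()[0]
                    chunks = []
                else:
                    chunks.append(line)
        if name is not None:
            arrays[name] = encode("".join(chunks))
        return cls(arrays)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f">{name}\n")
                seq = decode(self._chroms[name])
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def chrom_names(self) -> list[str]:
        return list(self._chroms)

    @property
    def sizes(self) -> dict[str, int]:
        return {name: len(arr) for name, arr in self._chroms.items()}

    def codes(self, chrom: str) -> np.ndarray:
        return self._chroms[chrom]

    def chrom_length(self, chrom: str) -> int:
        return len(self._chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        arr = self._chroms[chrom]
        start = max(0, start)
        end = min(len(arr), end)
        return decode(arr[start:end])

    def fetch_codes(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self._chroms[chrom][max(0, start) : end]

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)
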