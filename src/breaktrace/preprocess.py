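"""Raw read cleanup: adapter/quality trimming, demultiplexing, barcode
extraction and bait-primer verification.

The library layout this module expects (and the simulator emits):

* read 1 starts with the bait primer and reads from the primer across
  the cleavage site into whatever was joined there;
* read 2 starts with the bridge adapter — a 5' flank, a 14-nt random
  molecular barcode (RMB), a 3' flank — followed by the far end of the
  sonicated fragment.

Where exactly the RMB sits relative to the ligation point is a library
convention, not a biological fact; it is pinned down once here in
:class:`AdapterSpec` so the extractor and the simulator always agree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "RawReadPair",
    "CleanMolecule",
    "AdapterSpec",
    "ConfigError",
    "trim_read",
    "filter_short",
    "demultiplex",
    "extract_rmb",
    "verify_bait_primer",
    "preprocess_pairs",
]

RMB_LENGTH = 14

DEFAULT_SEQUENCING_ADAPTER = "AGATCGGAAGAGC"
DEFAULT_BRIDGE_TEMPLATE = "GTCGACGT" + "N" * RMB_LENGTH + "ACCTGCAG"


class ConfigError(ValueError):
    """Invalid run configuration (e.g. an ambiguous demultiplex table)."""


@dataclass
class RawReadPair:
    read_id: str
    read1_seq: str
    read1_quals: Sequence[int]
    read2_seq: str
    read2_quals: Sequence[int]
    index_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.read1_seq) != len(self.read1_quals):
            raise ValueError(f"{self.read_id}: read 1 sequence/quality length mismatch")
        if len(self.read2_seq) != len(self.read2_quals):
            raise ValueError(f"{self.read_id}: read 2 sequence/quality length mismatch")


@dataclass
class CleanMolecule:
    """One cleaned read pair ready for alignment.

    ``insert_seq`` is the trimmed read-1 sequence; it still begins with
    the (verified) bait primer so that alignments anchor on the primer
    interval. ``mate_seq`` is the read-2 sequence beyond the bridge
    adapter (prey-distal end of the fragment).
    """

    read_id: str
    rmb: str
    insert_seq: str
    mate_seq: str
    sample_id: str


@dataclass
class AdapterSpec:
    sequencing_adapter: str = DEFAULT_SEQUENCING_ADAPTER
    bridge_adapter_template: str = DEFAULT_BRIDGE_TEMPLATE
    bait_primer: str = ""
    quality_floor: int = 30
    min_adapter_overlap: int = 5

    def __post_init__(self) -> None:
        runs = re.findall(r"N+", self.bridge_adapter_template)
        if len(runs) != 1 or len(runs[0]) != RMB_LENGTH:
            raise ConfigError(
                "bridge adapter template must contain exactly one run "
                f"of {RMB_LENGTH} N's: {self.bridge_adapter_template!r}"
            )

    @property
    def bridge_flank5(self) -> str:
        return self.bridge_adapter_template.split("N", 1)[0]

    @property
    def bridge_flank3(self) -> str:
        return self.bridge_adapter_template.rsplit("N", 1)[1]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_read(seq: str, quals: Sequence[int], spec: AdapterSpec) -> tuple[str, list[int]]:
    """Remove a 3' sequencing-adapter occurrence, then low-quality tail bases.

    Adapter removal cuts at the leftmost full occurrence of the adapter,
    or at a read suffix matching an adapter prefix of at least
    ``min_adapter_overlap`` bases. Quality trimming then strips bases
    from the 3' end while their score is below ``quality_floor``. Both
    passes repeat until a fixed point, so trimming is idempotent.
    """
    seq = str(seq)
    quals = list(quals)
    adapter = spec.sequencing_adapter
    while True:
        before = len(seq)
        if adapter:
            hit = seq.find(adapter)
            if hit >= 0:
                seq, quals = seq[:hit], quals[:hit]
            else:
                max_ov = min(len(adapter) - 1, len(seq))
                for ov in range(max_ov, spec.min_adapter_overlap - 1, -1):
                    if seq.endswith(adapter[:ov]):
                        seq, quals = seq[:-ov], quals[:-ov]
                        break
        while quals and quals[-1] < spec.quality_floor:
            seq, quals = seq[:-1], quals[:-1]
        if len(seq) == before:
            return seq, quals


def filter_short(pairs: Iterable[RawReadPair], min_len: int = 25) -> list[RawReadPair]:
    """Keep pairs whose mates are both at least ``min_len`` bases, in order."""
    return [p for p in pairs if len(p.read1_seq) >= min_len and len(p.read2_seq) >= min_len]


def demultiplex(
    pairs: Iterable[RawReadPair],
    index_table: dict[str, str],
    max_mismatch: int = 1,
) -> dict[str, list[RawReadPair]]:
    """Assign pairs to samples by their index read.

    Returns a dict of sample id -> pairs plus an ``"undetermined"`` bin;
    the bins partition the input. The index table must be unambiguous:
    equal-length indices with pairwise Hamming distance > 2*max_mismatch.
    """
    indices = list(index_table)
    if indices:
        length = len(indices[0])
        if any(len(ix) != length for ix in indices):
            raise ConfigError("demultiplex indices must have equal length")
        for i, a in enumerate(indices):
            for b in indices[i + 1 :]:
                if _hamming(a, b) <= 2 * max_mismatch:
                    raise ConfigError(
                        f"indices {a} and {b} are within 2*max_mismatch of each other"
                    )
    bins: dict[str, list[RawReadPair]] = {sid: [] for sid in index_table.values()}
    bins["undetermined"] = []
    for pair in pairs:
        assigned = "undetermined"
        if pair.index_seq is not None:
            for ix, sid in index_table.items():
                if len(pair.index_seq) == len(ix) and _hamming(pair.index_seq, ix) <= max_mismatch:
                    assigned = sid
                    break
        bins[assigned].append(pair)
    return bins


def _find_flank(seq: str, flank: str, max_mismatch: int = 1) -> int:
    """Leftmost start of ``flank`` in ``seq`` allowing substitutions only."""
    exact = seq.find(flank)
    if exact >= 0:
        return exact
    for start in range(len(seq) - len(flank) + 1):
        if _hamming(seq[start : start + len(flank)], flank) <= max_mismatch:
            return start
    return -1


def extract_rmb(mate_seq: str, spec: AdapterSpec) -> Optional[tuple[str, str]]:
    """Locate the bridge adapter in a read-2 sequence and pull out the RMB.

    Each flank tolerates one substitution but no indels (the barcode
    must stay frame-aligned to be exactly 14 nt). Returns ``(rmb,
    sequence beyond the adapter)`` or ``None`` when the template is not
    found — a counted signal, not an error.
    """
    f5, f3 = spec.bridge_flank5, spec.bridge_flank3
    start = _find_flank(mate_seq, f5)
    if start < 0:
        return None
    rmb_start = start + len(f5)
    rmb_end = rmb_start + RMB_LENGTH
    f3_end = rmb_end + len(f3)
    if f3_end > len(mate_seq):
        return None
    if _hamming(mate_seq[rmb_end:f3_end], f3) > 1:
        return None
    return mate_seq[rmb_start:rmb_end], mate_seq[f3_end:]


def verify_bait_primer(read1_seq: str, spec: AdapterSpec) -> bool:
    """True iff read 1 begins with the bait primer (at most one mismatch)."""
    primer = spec.bait_primer
    if not primer or len(read1_seq) < len(primer):
        return False
    return _hamming(read1_seq[: len(primer)], primer) <= 1


def preprocess_pairs(
    pairs: Iterable[RawReadPair],
    spec: AdapterSpec,
    sample_id: str = "sample",
    min_len: int = 25,
) -> tuple[list[CleanMolecule], dict[str, int]]:
    """Trim, length-filter, extract RMBs and verify primers for one sample.

    Returns the cleaned molecules and a per-stage disposition count; the
    counts partition the input (``input == too_short + no_rmb +
    no_primer + clean``).
    """
    counts = {"input": 0, "too_short": 0, "no_rmb": 0, "no_primer": 0, "clean": 0}
    out: list[CleanMolecule] = []
    for pair in pairs:
        counts["input"] += 1
        seq1, quals1 = trim_read(pair.read1_seq, pair.read1_quals, spec)
        seq2, quals2 = trim_read(pair.read2_seq, pair.read2_quals, spec)
        if len(seq1) < min_len or len(seq2) < min_len:
            counts["too_short"] += 1
            continue
        hit = extract_rmb(seq2, spec)
        if hit is None:
            counts["no_rmb"] += 1
            continue
        rmb, mate_rest = hit
        if not verify_bait_primer(seq1, spec):
            counts["no_primer"] += 1
            continue
        counts["clean"] += 1
        out.append(
            CleanMolecule(
                read_id=pair.read_id,
                rmb=rmb,
                insert_seq=seq1,
                mate_seq=mate_rest,
                sample_id=sample_id,
            )
        )
    return out, counts
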