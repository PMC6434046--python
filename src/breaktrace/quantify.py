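"""Library-level quantities: G/I/T composition, editing efficiency,
junction profiles and the distal-resection fraction.

Editing efficiency compares the treated library's non-germline fraction
to an uncut control and divides by transfection efficiency (TE):

    efficiency = [ (I_s + T_s)/(G_s + I_s + T_s)
                 - (I_c + T_c)/(G_c + I_c + T_c) ] / TE

"Editing events" always means I + T — indels plus translocations — and
per-100,000-editing-events frequencies use that denominator.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .junctions import BaitConfig, JunctionCall

__all__ = [
    "LibraryStats",
    "EfficiencyResult",
    "tabulate",
    "editing_efficiency",
    "junction_profile",
    "resection_fraction",
]


@dataclass
class LibraryStats:
    G: int
    I: int
    T: int
    subcounts: dict[str, int] = field(default_factory=dict)
    label: str = ""

    @property
    def total(self) -> int:
        return self.G + self.I + self.T

    @property
    def editing_events(self) -> int:
        return self.I + self.T

    def raw_editing_fraction(self) -> float:
        if self.total == 0:
            raise ValueError(f"library {self.label!r} has no molecules")
        return self.editing_events / self.total


@dataclass
class EfficiencyResult:
    efficiency: float
    raw_sample_fraction: float
    raw_control_fraction: float
    te: float


def tabulate(calls: Iterable[JunctionCall], label: str = "") -> LibraryStats:
    """Count deduplicated, classified calls by category and subcategory."""
    cat = Counter()
    sub = Counter()
    for call in calls:
        if call.category not in ("germline", "indel", "translocation"):
            raise ValueError(f"unclassified call: {call!r}")
        cat[call.category] += 1
        sub[call.subcategory] += 1
    return LibraryStats(
        G=cat["germline"],
        I=cat["indel"],
        T=cat["translocation"],
        subcounts=dict(sorted(sub.items())),
        label=label,
    )


def editing_efficiency(sample: LibraryStats, control: LibraryStats, te: float = 1.0) -> EfficiencyResult:
    """Control-subtracted, transfection-corrected editing efficiency.

    Negative values (control noise exceeding the sample signal) clamp
    to 0 with a warning rather than erroring; values above 1 likewise
    clamp, which can occur when TE is underestimated.
    """
    if not 0.0 < te <= 1.0:
        raise ValueError(f"transfection efficiency must be in (0, 1], got {te}")
    raw_s = sample.raw_editing_fraction()
    raw_c = control.raw_editing_fraction()
    eff = (raw_s - raw_c) / te
    if eff < 0.0:
        warnings.warn(
            f"control editing fraction ({raw_c:.4g}) exceeds sample ({raw_s:.4g}); "
            "clamping efficiency to 0",
            stacklevel=2,
        )
        eff = 0.0
    elif eff > 1.0:
        warnings.warn(f"efficiency {eff:.4g} > 1 after TE correction; clamping to 1", stacklevel=2)
        eff = 1.0
    return EfficiencyResult(eff, raw_s, raw_c, te)


def junction_profile(
    junctions: Sequence[tuple[int, str]],
    center: int,
    window: int = 5000,
    binsize: int = 50,
    split_by_orientation: bool = True,
) -> dict[str, np.ndarray]:
    """Bin junction coordinates around a center position.

    ``junctions`` holds (coordinate, strand) pairs. Bins cover
    ``[center - window, center + window)``; the last bin is truncated
    when ``binsize`` does not divide ``2 * window``. Returns arrays per
    orientation (plus a combined "all" track); each array sums to the
    number of junctions inside the window.
    """
    if binsize <= 0 or window <= 0:
        raise ValueError("window and binsize must be positive")
    n_bins = -(-2 * window // binsize)
    start = center - window
    tracks: dict[str, np.ndarray] = {"all": np.zeros(n_bins, dtype=int)}
    if split_by_orientation:
        tracks["+"] = np.zeros(n_bins, dtype=int)
        tracks["-"] = np.zeros(n_bins, dtype=int)
    for coord, strand in junctions:
        offset = coord - start
        if not 0 <= offset < 2 * window:
            continue
        b = offset // binsize
        tracks["all"][b] += 1
        if split_by_orientation and strand in tracks:
            tracks[strand][b] += 1
    return tracks


def _is_deletion_consistent(call: JunctionCall, bait: BaitConfig) -> bool:
    prey = call.prey
    if prey is None or prey.chrom != bait.chrom or prey.strand != bait.strand:
        return False
    offset = prey.coord - bait.cut_pos
    return offset >= 0 if bait.strand == "+" else offset <= 0


def resection_fraction(
    stats: LibraryStats,
    calls: Iterable[JunctionCall],
    bait: BaitConfig,
    region: tuple[int, int] = (5_000, 50_000),
) -> float:
    """Fraction of editing events rejoined 5-50 kb downstream of the cut.

    Counts deletion-consistent junctions (same chromosome and strand as
    the bait, downstream of the cut) whose distance from the cut lies in
    ``region``, over I + T editing events.
    """
    lo, hi = region
    if stats.editing_events == 0:
        raise ValueError("no editing events in library")
    n = 0
    for call in calls:
        if not _is_deletion_consistent(call, bait):
            continue
        if lo <= abs(call.prey.coord - bait.cut_pos) <= hi:
            n += 1
    return n / stats.editing_events
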