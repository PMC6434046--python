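"""Junction detection and molecule classification.

Each sequenced molecule is anchored at the bait primer; its alignment
evidence is a group of :class:`AlignedSegment` records in query order.
The first (bait) segment must overlap the primer interval. A second
segment, if present, is the prey; its query-proximal reference
coordinate is the junction. Molecules are classified as germline, indel
(small or resection-scale) or genome-wide translocation.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "BaitConfig",
    "Edit",
    "AlignedSegment",
    "PreyLocus",
    "JunctionCall",
    "CATEGORIES",
    "SUBCATEGORIES",
    "group_alignments",
    "call_junction",
    "classify",
    "split_translocations",
]

CATEGORIES = ("germline", "indel", "translocation")
SUBCATEGORIES = (
    "perfect",
    "small_insertion",
    "small_deletion",
    "insertion_plus_deletion",
    "large_deletion",
    "inversion",
    "offtarget_translocation",
    "background_translocation",
)

#: BEDPE score codes, one per subcategory.
SUBCATEGORY_CODES = {name: i for i, name in enumerate(SUBCATEGORIES)}


@dataclass(frozen=True)
class BaitConfig:
    """The fixed, primer-anchored locus under study."""

    chrom: str
    strand: str
    primer_start: int
    primer_end: int
    cut_pos: int
    guide_seq: str
    pam: str = "NGG"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bait strand must be + or -, got {self.strand!r}")
        if len(self.guide_seq) != 20:
            raise ValueError("guide sequence must be 20 nt")
        if not self.primer_start < self.primer_end:
            raise ValueError("empty primer interval")
        if min(abs(self.cut_pos - self.primer_start), abs(self.cut_pos - self.primer_end)) > 200:
            raise ValueError("bait primer must lie within 200 bp of the cleavage site")


@dataclass(frozen=True)
class Edit:
    """A non-match alignment operation on the reference.

    ``op`` is "I" (insertion of ``length`` query bases before reference
    position ``pos``), "D" (deletion of reference interval
    ``[pos, pos+length)``) or "X" (substitution run). Only I and D count
    toward indel classification.
    """

    op: str
    pos: int
    length: int


@dataclass
class AlignedSegment:
    chrom: str
    start: int
    end: int
    strand: str
    query_start: int
    query_end: int
    n_mismatch: int = 0
    edits: tuple[Edit, ...] = ()
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment reference interval is empty")

    @property
    def query_length(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class PreyLocus:
    chrom: str
    coord: int
    strand: str


@dataclass
class JunctionCall:
    rmb: str
    bait_end: int
    prey: Optional[PreyLocus]
    category: str = ""
    subcategory: str = ""
    cut_window_edits: tuple[Edit, ...] = ()
    molecule_id: str = ""

    @property
    def junction_pos(self) -> int:
        return self.prey.coord if self.prey is not None else self.bait_end


def group_alignments(
    records: Iterable[tuple[str, str, Sequence[AlignedSegment]]],
    min_mapq: int = 1,
) -> tuple[list[tuple[str, str, list[AlignedSegment]]], int]:
    """Collect per-molecule segment groups, dropping non-unique bait mappings.

    ``records`` yields (molecule_id, rmb, segments). The bait segment is
    the query-first one; a molecule whose bait segment falls below
    ``min_mapq`` is dropped. Returns the kept groups and the dropped
    count.
    """
    groups: list[tuple[str, str, list[AlignedSegment]]] = []
    dropped = 0
    for mol_id, rmb, segments in records:
        if not rmb:
            raise ValueError(f"molecule {mol_id} is missing its RMB tag")
        segs = sorted(segments, key=lambda s: s.query_start)
        if not segs or segs[0].mapq < min_mapq:
            dropped += 1
            continue
        groups.append((mol_id, rmb, segs))
    return groups, dropped


def call_junction(
    group: Sequence[AlignedSegment],
    bait: BaitConfig,
    rmb: str = "",
    molecule_id: str = "",
    min_prey_len: int = 20,
    max_prey_edit_rate: float = 0.10,
) -> Optional[JunctionCall]:
    """Locate the bait->prey junction for one molecule.

    Returns ``None`` (a counted "bait-less" disposition) when no segment
    overlaps the bait primer on the bait strand. ``bait_end`` is the
    reference coordinate where the bait-anchored alignment stops — the
    far end from the primer. A second segment becomes the prey if it is
    at least ``min_prey_len`` long with an edit rate at most
    ``max_prey_edit_rate``; its proximal (junction-facing) coordinate is
    the start for a plus-strand prey and the end for a minus-strand one.
    """
    segs = sorted(group, key=lambda s: s.query_start)
    if not segs:
        return None
    bait_seg = segs[0]
    if (
        bait_seg.chrom != bait.chrom
        or bait_seg.strand != bait.strand
        or bait_seg.end <= bait.primer_start
        or bait_seg.start >= bait.primer_end
    ):
        return None
    bait_end = bait_seg.end if bait.strand == "+" else bait_seg.start
    prey = None
    for seg in segs[1:]:
        if seg.query_length < min_prey_len:
            continue
        if seg.n_mismatch > max_prey_edit_rate * seg.query_length:
            continue
        coord = seg.start if seg.strand == "+" else seg.end
        prey = PreyLocus(seg.chrom, coord, seg.strand)
        break
    edits = tuple(e for s in segs for e in s.edits)
    return JunctionCall(
        rmb=rmb,
        bait_end=bait_end,
        prey=prey,
        cut_window_edits=edits,
        molecule_id=molecule_id,
    )


def _edit_in_window(edit: Edit, cut_pos: int, window: int) -> bool:
    """cut_pos is a boundary coordinate (between two bases), so the
    symmetric window covers base positions [cut-w, cut+w-1] for
    deletions and boundary positions [cut-w, cut+w] for insertions."""
    lo, hi = cut_pos - window, cut_pos + window
    if edit.op == "I":
        return lo <= edit.pos <= hi
    if edit.op == "D":
        return edit.pos <= hi - 1 and edit.pos + edit.length - 1 >= lo
    return False


def classify(
    call: JunctionCall,
    bait: BaitConfig,
    indel_window: int = 5,
    proximal_span: int = 250_000,
) -> JunctionCall:
    """Assign category and subcategory to a junction call.

    Rules, applied in order:

    * a prey on the bait chromosome within ``proximal_span`` of the cut
      (inclusive) is a rejoining event, counted as an indel — subcategory
      ``inversion`` when strand-flipped relative to the bait, otherwise
      ``large_deletion``;
    * a prey beyond the span or on another chromosome is a translocation;
    * without a prey, insertion/deletion edits inside the symmetric
      ``indel_window`` around the cut boundary (deleted bases in
      ``[cut-w, cut+w-1]``, insertion points in ``[cut-w, cut+w]``) make
      the molecule an indel (``small_insertion`` / ``small_deletion`` /
      ``insertion_plus_deletion``); otherwise it is germline.

    Substitution-only edits never leave the germline category.
    """
    if call.prey is not None:
        prey = call.prey
        if prey.chrom == bait.chrom and abs(prey.coord - bait.cut_pos) <= proximal_span:
            sub = "inversion" if prey.strand != bait.strand else "large_deletion"
            return replace(call, category="indel", subcategory=sub)
        return replace(call, category="translocation", subcategory="background_translocation")
    hits = [e for e in call.cut_window_edits if _edit_in_window(e, bait.cut_pos, indel_window)]
    has_ins = any(e.op == "I" for e in hits)
    has_del = any(e.op == "D" for e in hits)
    if has_ins and has_del:
        return replace(call, category="indel", subcategory="insertion_plus_deletion")
    if has_ins:
        return replace(call, category="indel", subcategory="small_insertion")
    if has_del:
        return replace(call, category="indel", subcategory="small_deletion")
    return replace(call, category="germline", subcategory="perfect")


def split_translocations(
    calls: Iterable[JunctionCall],
    hotspot_cuts: Sequence[tuple[str, int]],
    window: int = 500,
) -> dict[str, int]:
    """Tally translocations as off-target versus genome-wide background.

    A translocation is off-target when its junction lies within
    ``window`` bp of any hotspot's presumed cut site. The two tallies sum
    to the number of translocation calls; the calls' subcategories are
    updated in place.
    """
    tallies = {"offtarget_translocation": 0, "background_translocation": 0}
    for call in calls:
        if call.category != "translocation":
            continue
        prey = call.prey
        is_hot = any(
            prey is not None and prey.chrom == chrom and abs(prey.coord - cut) <= window
            for chrom, cut in hotspot_cuts
        )
        sub = "offtarget_translocation" if is_hot else "background_translocation"
        call.subcategory = sub
        tallies[sub] += 1
    return tallies
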