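"""File formats: FASTQ, SAM (via pysam), BEDPE junction records, TSV
reports. All coordinates in files follow BED conventions (0-based
half-open)."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

from .junctions import (
    AlignedSegment,
    Edit,
    JunctionCall,
    PreyLocus,
    SUBCATEGORY_CODES,
)
from .preprocess import CleanMolecule, RawReadPair

__all__ = [
    "read_fastq_pairs",
    "write_fastq_pairs",
    "write_clean_fastq",
    "write_sam",
    "read_sam_groups",
    "write_junction_bedpe",
    "read_junction_bedpe",
    "write_counts_tsv",
    "write_json",
]

_CODE_TO_SUB = {v: k for k, v in SUBCATEGORY_CODES.items()}


def _open(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_fastq(handle) -> Iterator[tuple[str, str, list[int]]]:
    while True:
        header = handle.readline()
        if not header:
            return
        seq = handle.readline().strip()
        handle.readline()
        quals = handle.readline().strip()
        yield header.strip()[1:], seq, [ord(c) - 33 for c in quals]


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[RawReadPair]:
    """Stream paired FASTQ (Phred+33, optionally gzipped).

    An index sequence may ride in the read-1 header as a trailing
    ``IDX:<seq>`` token.
    """
    with _open(r1_path) as h1, _open(r2_path) as h2:
        for (id1, s1, q1), (id2, s2, q2) in zip(_parse_fastq(h1), _parse_fastq(h2)):
            fields = id1.split()
            index_seq = None
            for tok in fields[1:]:
                if tok.startswith("IDX:"):
                    index_seq = tok[4:]
            yield RawReadPair(fields[0], s1, q1, s2, q2, index_seq=index_seq)


def write_fastq_pairs(pairs: Iterable[RawReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    with _open(r1_path, "wt") as h1, _open(r2_path, "wt") as h2:
        for p in pairs:
            idx = f" IDX:{p.index_seq}" if p.index_seq else ""
            h1.write(f"@{p.read_id}{idx}\n{p.read1_seq}\n+\n")
            h1.write("".join(chr(q + 33) for q in p.read1_quals) + "\n")
            h2.write(f"@{p.read_id}\n{p.read2_seq}\n+\n")
            h2.write("".join(chr(q + 33) for q in p.read2_quals) + "\n")


def write_clean_fastq(molecules: Iterable[CleanMolecule], path: str | Path) -> None:
    """Interleaved cleaned molecules; the RMB rides in the header."""
    with _open(path, "wt") as fh:
        for m in molecules:
            fh.write(f"@{m.read_id} RMB:Z:{m.rmb}\n{m.insert_seq}\n+\n{'I' * len(m.insert_seq)}\n")
            fh.write(f"@{m.read_id}/2 RMB:Z:{m.rmb}\n{m.mate_seq}\n+\n{'I' * len(m.mate_seq)}\n")


# ---- SAM ------------------------------------------------------------


def _cigar_for(seg: AlignedSegment, read_len: int) -> list[tuple[int, int]]:
    """CIGAR in reference orientation; M/I/D plus soft clips."""
    ref_span = seg.end - seg.start
    q_span = seg.query_end - seg.query_start
    dels = sorted((e for e in seg.edits if e.op == "D"), key=lambda e: e.pos)
    ins = sorted((e for e in seg.edits if e.op == "I"), key=lambda e: e.pos)
    d_total = sum(e.length for e in dels)
    i_total = sum(e.length for e in ins)
    events = sorted(
        [(e.pos, "D", e.length) for e in dels] + [(e.pos, "I", e.length) for e in ins],
        key=lambda t: (t[0], t[1]),
    )
    ops: list[tuple[int, int]] = []
    rpos = seg.start
    consumed_q = 0
    for pos, op, length in events:
        m = pos - rpos
        if m > 0:
            ops.append((0, m))
            consumed_q += m
        if op == "D":
            ops.append((2, length))
            rpos = pos + length
        else:
            ops.append((1, length))
            consumed_q += length
            rpos = pos
    tail_ref = seg.end - rpos
    if tail_ref > 0:
        ops.append((0, tail_ref))
        consumed_q += tail_ref
    if consumed_q != q_span:  # substitution-only bookkeeping mismatch
        raise ValueError(
            f"segment query span {q_span} inconsistent with edits (consumed {consumed_q})"
        )
    if seg.strand == "+":
        pre, post = seg.query_start, read_len - seg.query_end
    else:
        # stored SEQ is the reverse complement, so clips swap ends
        pre, post = read_len - seg.query_end, seg.query_start
    full = []
    if pre:
        full.append((4, pre))
    full.extend(ops)
    if post:
        full.append((4, post))
    return full


def write_sam(
    path: str | Path,
    genome_sizes: dict[str, int],
    aligned: Iterable[tuple[str, str, Sequence[AlignedSegment], str]],
) -> None:
    """Write per-molecule alignments as SAM text.

    ``aligned`` yields (molecule_id, rmb, segments-in-query-order,
    read_sequence). The first segment is primary; later ones carry the
    supplementary flag. Unaligned molecules (no segments) get an
    unmapped record.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": size} for name, size in genome_sizes.items()],
    }
    tid = {name: i for i, name in enumerate(genome_sizes)}
    from .genome import encode, decode, revcomp_codes

    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for mol_id, rmb, segments, seq in aligned:
            if not segments:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = mol_id
                rec.flag = 4
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                rec.set_tag("RX", rmb)
                out.write(rec)
                continue
            for i, seg in enumerate(segments):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = mol_id
                rec.flag = (16 if seg.strand == "-" else 0) | (2048 if i > 0 else 0)
                rec.reference_id = tid[seg.chrom]
                rec.reference_start = seg.start
                rec.mapping_quality = seg.mapq
                rec.cigartuples = _cigar_for(seg, len(seq))
                rseq = seq if seg.strand == "+" else decode(revcomp_codes(encode(seq)))
                rec.query_sequence = rseq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(rseq))
                nm = seg.n_mismatch + sum(e.length for e in seg.edits if e.op in "ID")
                rec.set_tag("NM", nm)
                rec.set_tag("RX", rmb)
                out.write(rec)


def read_sam_groups(path: str | Path) -> Iterator[tuple[str, str, list[AlignedSegment]]]:
    """Yield (molecule_id, rmb, segments) groups from a SAM/BAM file.

    Records must carry the RMB in the ``RX`` tag; query coordinates are
    reported in original-read orientation so segments sort correctly by
    query position.
    """
    current: Optional[str] = None
    rmb = ""
    segs: list[AlignedSegment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.query_name != current:
                if current is not None:
                    yield current, rmb, segs
                current = rec.query_name
                rmb = rec.get_tag("RX") if rec.has_tag("RX") else ""
                segs = []
            if rec.is_unmapped:
                continue
            read_len = rec.infer_read_length() or 0
            if rec.is_reverse:
                qstart = read_len - rec.query_alignment_end
                qend = read_len - rec.query_alignment_start
            else:
                qstart = rec.query_alignment_start
                qend = rec.query_alignment_end
            edits = []
            rpos = rec.reference_start
            indel_len = 0
            for op, length in rec.cigartuples or ():
                if op in (0, 7, 8):  # M/=/X
                    rpos += length
                elif op == 2:  # D
                    edits.append(Edit("D", rpos, length))
                    rpos += length
                    indel_len += length
                elif op == 1:  # I
                    edits.append(Edit("I", rpos, length))
                    indel_len += length
            nm = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
            segs.append(
                AlignedSegment(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    query_start=qstart,
                    query_end=qend,
                    n_mismatch=max(0, nm - indel_len),
                    edits=tuple(edits),
                    mapq=rec.mapping_quality,
                )
            )
    if current is not None:
        yield current, rmb, segs


# ---- BEDPE ----------------------------------------------------------


def write_junction_bedpe(calls: Iterable[JunctionCall], path: str | Path, bait_chrom: str, bait_strand: str) -> None:
    """One record per molecule: bait side, prey side (or ./-1), name=RMB,
    score=subcategory code, then category/subcategory columns."""
    with _open(path, "wt") as fh:
        for c in calls:
            if c.prey is not None:
                p = c.prey
                prey_cols = (p.chrom, p.coord, p.coord + 1, p.strand)
            else:
                prey_cols = (".", -1, -1, ".")
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        bait_chrom,
                        c.bait_end,
                        c.bait_end + 1,
                        prey_cols[0],
                        prey_cols[1],
                        prey_cols[2],
                        c.rmb,
                        SUBCATEGORY_CODES.get(c.subcategory, -1),
                        bait_strand,
                        prey_cols[3],
                        c.category,
                        c.subcategory,
                        c.molecule_id,
                    )
                )
                + "\n"
            )


def read_junction_bedpe(path: str | Path) -> list[JunctionCall]:
    calls = []
    with _open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            prey = None
            if f[3] != ".":
                prey = PreyLocus(f[3], int(f[4]), f[9])
            calls.append(
                JunctionCall(
                    rmb=f[6],
                    bait_end=int(f[1]),
                    prey=prey,
                    category=f[10],
                    subcategory=f[11],
                    molecule_id=f[12] if len(f) > 12 else "",
                )
            )
    return calls


def write_counts_tsv(counts: dict[str, int | float], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        fh.write("key\tvalue\n")
        for key, value in counts.items():
            fh.write(f"{key}\t{value}\n")


def write_json(obj, path: str | Path) -> None:
    with _open(path, "wt") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
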