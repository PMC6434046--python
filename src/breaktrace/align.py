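"""Exact-seed toy aligner for simulated reads on small genomes.

This exists so the test suite never shells out to an external mapper:
it is adequate for error-free or low-error simulated reads against toy
references (sorted k-mer index, ungapped diagonal extension, split
segments at junctions, small-gap merging into indel edits). It is not
intended for real sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genome import Genome, encode, revcomp_codes
from .junctions import AlignedSegment, Edit

__all__ = ["ToyAligner"]

MAX_INDEX_BP = 100_000_000


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    c = codes.astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        seg = c[i : i + n]
        out = (out << np.uint64(2)) | (seg & np.uint64(3))
        valid &= seg < 4
    return out, valid


@dataclass
class _RawSegment:
    chrom: str
    start: int
    end: int
    strand: str
    qstart: int
    qend: int
    n_mismatch: int
    seed_count: int
    ambiguous: bool


class ToyAligner:
    def __init__(self, genome: Genome, k: int = 20, stride: int = 4, max_hits: int = 64) -> None:
        total = sum(genome.sizes.values())
        if total > MAX_INDEX_BP:
            raise ValueError("toy aligner refuses genomes over ~100 Mb")
        self.genome = genome
        self.k = k
        self.stride = stride
        self.max_hits = max_hits
        self.chrom_names = genome.chrom_names
        self._offsets = {}
        codes_list, pos_list = [], []
        offset = 0
        for name in self.chrom_names:
            arr = genome.codes(name)
            self._offsets[name] = offset
            kc, valid = _kmer_codes(arr, k)
            take = np.arange(0, len(kc), stride)
            take = take[valid[take]]
            codes_list.append(kc[take])
            pos_list.append(take + offset)
            offset += len(arr)
        self._total = offset
        allc = np.concatenate(codes_list) if codes_list else np.empty(0, dtype=np.uint64)
        allp = np.concatenate(pos_list) if pos_list else np.empty(0, dtype=np.int64)
        order = np.argsort(allc, kind="stable")
        self._idx_codes = allc[order]
        self._idx_pos = allp[order].astype(np.int64)
        self._bounds = np.array(
            [self._offsets[n] for n in self.chrom_names] + [self._total], dtype=np.int64
        )

    def _locate(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self._bounds, gpos, side="right")) - 1
        name = self.chrom_names[ci]
        return name, gpos - self._offsets[name]

    # ---- seeding -----------------------------------------------------

    def _diagonals(self, codes: np.ndarray) -> dict[int, list[int]]:
        """Map global diagonal (gpos - qoffset) -> seed query offsets."""
        kc, valid = _kmer_codes(codes, self.k)
        if len(kc) == 0:
            return {}
        lo = np.searchsorted(self._idx_codes, kc, side="left")
        hi = np.searchsorted(self._idx_codes, kc, side="right")
        diags: dict[int, list[int]] = {}
        for q in range(len(kc)):
            if not valid[q] or hi[q] - lo[q] == 0 or hi[q] - lo[q] > self.max_hits:
                continue
            for p in self._idx_pos[lo[q] : hi[q]]:
                diags.setdefault(int(p) - q, []).append(q)
        return diags

    def _extend(self, rcodes: np.ndarray, diag: int, seeds: list[int]) -> Optional[tuple]:
        """Ungapped extension along one diagonal; stops at two consecutive
        mismatches, trims flanking mismatches."""
        chrom, local0 = self._locate(diag + seeds[0])
        carr = self.genome.codes(chrom)
        coff = self._offsets[chrom]
        d = diag - coff  # local diagonal: ref = q + d
        qmin = max(0, -d)
        qmax = min(len(rcodes), len(carr) - d)
        if qmax - qmin < self.k:
            return None
        eq = (rcodes[qmin:qmax] == carr[qmin + d : qmax + d]) & (rcodes[qmin:qmax] < 4)

        def _walk(idx: int, step: int) -> int:
            consec = 0
            last = idx
            j = idx + step
            while 0 <= j < len(eq):
                if eq[j]:
                    consec = 0
                    last = j
                else:
                    consec += 1
                    if consec >= 2:
                        break
                j += step
            return last

        s0 = seeds[0] - qmin
        s1 = min(seeds[-1] + self.k - 1, qmax - 1) - qmin
        left = _walk(s0, -1)
        right = _walk(s1, +1)
        while left < right and not eq[left]:
            left += 1
        while right > left and not eq[right]:
            right -= 1
        qs, qe = qmin + left, qmin + right + 1
        if qe - qs < self.k:
            return None
        nmm = int((~eq[left : right + 1]).sum())
        return chrom, qs + d, qe + d, qs, qe, nmm

    def _best_segment(self, rcodes_f: np.ndarray) -> Optional[_RawSegment]:
        rcodes_r = revcomp_codes(rcodes_f)
        cands: list[tuple[int, int, str, list[int]]] = []
        for strand, rc in (("+", rcodes_f), ("-", rcodes_r)):
            for diag, seeds in self._diagonals(rc).items():
                cands.append((len(seeds), diag, strand, seeds))
        if not cands:
            return None
        cands.sort(key=lambda t: (-t[0], t[2], t[1]))
        best = cands[0]
        ambiguous = False
        for other in cands[1:]:
            if other[0] < best[0]:
                break
            if other[2] != best[2] or abs(other[1] - best[1]) > 2 * self.k:
                ambiguous = True
                break
        rc = rcodes_f if best[2] == "+" else rcodes_r
        ext = self._extend(rc, best[1], sorted(best[3]))
        if ext is None:
            return None
        chrom, start, end, qs, qe, nmm = ext
        n = len(rcodes_f)
        if best[2] == "-":
            qs, qe = n - qe, n - qs
        return _RawSegment(chrom, start, end, best[2], qs, qe, nmm, best[0], ambiguous)

    # ---- public API --------------------------------------------------

    def align(self, seq: str, min_remainder: int = 23) -> list[AlignedSegment]:
        """Align one read; returns 0, 1 or 2 segments in query order.

        After the primary segment, the longest uncovered read end (if at
        least ``min_remainder`` nt) is aligned to produce a split
        (prey) segment; collinear segments separated by a small gap are
        merged into one segment carrying insertion/deletion edits.
        """
        min_remainder = max(min_remainder, self.k + self.stride - 1)
        rcodes = encode(seq)
        primary = self._best_segment(rcodes)
        if primary is None:
            return []
        segs = [primary]
        # widen each remainder window into the primary segment: its
        # extension may have absorbed chance matches past the junction,
        # and boundary refinement needs an overlap to repartition
        margin = 15
        for lo, hi, wlo, whi in (
            (0, primary.qstart, 0, min(len(seq), primary.qstart + margin)),
            (primary.qend, len(seq), max(0, primary.qend - margin), len(seq)),
        ):
            if hi - lo < min_remainder:
                continue
            sub = self._best_segment(rcodes[wlo:whi])
            if sub is None:
                continue
            sub.qstart += wlo
            sub.qend += wlo
            segs.append(sub)
        segs.sort(key=lambda s: s.qstart)
        merged = self._merge(rcodes, segs)
        out = []
        for s, edits in merged:
            out.append(
                AlignedSegment(
                    chrom=s.chrom,
                    start=s.start,
                    end=s.end,
                    strand=s.strand,
                    query_start=s.qstart,
                    query_end=s.qend,
                    n_mismatch=s.n_mismatch,
                    edits=tuple(edits),
                    mapq=0 if s.ambiguous else 60,
                )
            )
        return out

    def _merge(self, rcodes: np.ndarray, segs: list[_RawSegment]) -> list[tuple[_RawSegment, list[Edit]]]:
        out: list[tuple[_RawSegment, list[Edit]]] = []
        for seg in segs:
            if not out:
                out.append((seg, []))
                continue
            prev, edits = out[-1]
            joined = self._try_indel_join(rcodes, prev, seg, edits)
            if joined is not None:
                out[-1] = joined
                continue
            a, b = self._refine_boundary(rcodes, prev, seg)
            if a is None:
                out.pop()
                if b is not None:
                    out.append((b, []))
            elif b is None:
                out[-1] = (a, edits)
            else:
                out[-1] = (a, edits)
                out.append((b, []))
        return out

    def _match_profile(self, rcodes: np.ndarray, seg: _RawSegment, qlo: int, qhi: int) -> np.ndarray:
        """Per-query-base match indicator against ``seg``'s alignment frame,
        evaluated over [qlo, qhi) (positions outside the reference count
        as mismatches)."""
        arr = self.genome.codes(seg.chrom)
        q = np.arange(qlo, qhi)
        if seg.strand == "+":
            r = q + (seg.start - seg.qstart)
            ref = np.where((r >= 0) & (r < len(arr)), arr[np.clip(r, 0, len(arr) - 1)], 255)
        else:
            r = (seg.start + seg.qend - 1) - q
            raw = np.where((r >= 0) & (r < len(arr)), arr[np.clip(r, 0, len(arr) - 1)], 255)
            comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
            ref = np.where(raw < 5, comp[np.clip(raw, 0, 4)], 255)
        read = rcodes[qlo:qhi]
        return (read == ref) & (read < 4)

    def _try_indel_join(
        self, rcodes: np.ndarray, a: _RawSegment, b: _RawSegment, edits: list[Edit]
    ) -> Optional[tuple[_RawSegment, list[Edit]]]:
        """Join two collinear-ish segments into one carrying I/D edits.

        The breakpoint is refined by maximizing matches of a read prefix
        in a's frame plus a suffix in b's frame (leftmost optimum, i.e.
        left-aligned indels); inserted bases are unscored.
        """
        if a.chrom != b.chrom or a.strand != b.strand:
            return None
        if a.strand == "+":
            delta = (b.start - b.qstart) - (a.start - a.qstart)
        else:
            delta = (a.start + a.qend) - (b.start + b.qend)
        if not -12 <= delta <= 60:
            return None
        qgap = b.qstart - a.qend
        if not -16 <= qgap <= 16:
            return None
        ins = max(0, -delta)
        dele = max(0, delta)
        qlo, qhi = a.qstart, b.qend
        if qhi - qlo - ins < self.k:
            return None
        eq_a = self._match_profile(rcodes, a, qlo, qhi)
        eq_b = self._match_profile(rcodes, b, qlo, qhi)
        n = qhi - qlo
        pref = np.concatenate([[0], np.cumsum(eq_a)])
        suff = np.concatenate([np.cumsum(eq_b[::-1])[::-1], [0]])
        # q1 = breakpoint (end of prefix), inserted bases occupy [q1, q1+ins)
        idx = np.arange(0, n - ins + 1)
        scores = pref[idx] + suff[idx + ins]
        best = int(np.argmax(scores))
        score = int(scores[best])
        scored = n - ins
        nmm = scored - score
        if delta == 0 and nmm > 0.2 * scored:
            return None
        if delta != 0 and nmm > 0.1 * scored:
            return None
        q1 = qlo + best
        new_edits = list(edits)
        if a.strand == "+":
            start = a.start - a.qstart + qlo
            end = b.start - b.qstart + qhi
            rj = q1 + (a.start - a.qstart)
        else:
            start = (b.start + b.qend) - qhi
            end = (a.start + a.qend) - qlo
            rj = (b.start + b.qend - 1) - (q1 + ins) + 1
        if dele > 0:
            new_edits.append(Edit("D", rj, dele))
        if ins > 0:
            new_edits.append(Edit("I", rj, ins))
        merged = _RawSegment(
            a.chrom,
            start,
            end,
            a.strand,
            qlo,
            qhi,
            nmm,
            a.seed_count + b.seed_count,
            a.ambiguous or b.ambiguous,
        )
        return merged, new_edits

    def _refine_boundary(
        self, rcodes: np.ndarray, a: _RawSegment, b: _RawSegment
    ) -> Optional[tuple[_RawSegment, _RawSegment]]:
        """Resolve a query overlap between two true split segments.

        Chance matches let both extensions overshoot the junction; the
        overlapping query bases are repartitioned at the split point
        maximizing total matches (leftmost optimum). A segment whose
        aligned part would shrink below k is dropped (returned as
        None in its slot)."""
        if b.qstart >= a.qend:
            return a, b
        qlo, qhi = b.qstart, a.qend
        eq_a = self._match_profile(rcodes, a, qlo, qhi)
        eq_b = self._match_profile(rcodes, b, qlo, qhi)
        n = qhi - qlo
        pref = np.concatenate([[0], np.cumsum(eq_a)])
        suff = np.concatenate([np.cumsum(eq_b[::-1])[::-1], [0]])
        scores = pref + suff
        # rightmost optimum: ambiguous (microhomologous) bases go to the
        # bait side, so the prey coordinate lands on the true junction
        q_star = qlo + (len(scores) - 1 - int(np.argmax(scores[::-1])))
        return self._set_qend(a, q_star), self._set_qstart(b, q_star)

    def _set_qend(self, seg: _RawSegment, qend: int) -> Optional[_RawSegment]:
        trim = seg.qend - qend
        if trim <= 0:
            return seg
        if seg.qend - seg.qstart - trim < self.k:
            return None
        if seg.strand == "+":
            return _RawSegment(seg.chrom, seg.start, seg.end - trim, seg.strand,
                              seg.qstart, qend, seg.n_mismatch, seg.seed_count, seg.ambiguous)
        return _RawSegment(seg.chrom, seg.start + trim, seg.end, seg.strand,
                          seg.qstart, qend, seg.n_mismatch, seg.seed_count, seg.ambiguous)

    def _set_qstart(self, seg: _RawSegment, qstart: int) -> Optional[_RawSegment]:
        trim = qstart - seg.qstart
        if trim <= 0:
            return seg
        if seg.qend - seg.qstart - trim < self.k:
            return None
        if seg.strand == "+":
            return _RawSegment(seg.chrom, seg.start + trim, seg.end, seg.strand,
                              qstart, seg.qend, seg.n_mismatch, seg.seed_count, seg.ambiguous)
        return _RawSegment(seg.chrom, seg.start, seg.end - trim, seg.strand,
                          qstart, seg.qend, seg.n_mismatch, seg.seed_count, seg.ambiguous)
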