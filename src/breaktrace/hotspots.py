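"""Genome-wide off-target hotspot identification.

The workflow mirrors a translocation-junction peak analysis at fixed
parameters: junctions proximal to the bait are excluded, each remaining
junction is extended to a small fixed footprint, contiguous pile-ups
become candidate regions, and each candidate's junction count is tested
against a local Poisson rate — the maximum of the genome-wide rate and
the rate in a large surrounding span. Benjamini-Hochberg correction is
applied over the effective number of genome-wide windows. Surviving
candidates must carry a cryptic target-like sequence, at least
``min_junctions`` pooled junctions within ``count_window`` of the
presumed cut, and support from at least ``min_replicates`` replicate
libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .junctions import BaitConfig

__all__ = [
    "PeakParams",
    "CandidateRegion",
    "TargetMatch",
    "Hotspot",
    "call_enriched_regions",
    "find_cryptic_site",
    "filter_and_merge",
    "hotspot_intensity",
    "directional_balance",
]

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC codes needed for PAM patterns.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PeakParams:
    extsize: int = 50
    q_threshold: float = 0.05
    local_background_span: int = 10_000_000
    exclusion_span: int = 250_000
    min_junctions: int = 3
    count_window: int = 500
    min_replicates: int = 2
    max_mismatches: int = 6
    pam_patterns: tuple[str, ...] = ("NGG", "NAG")
    cryptic_slop: int = 50

    def __post_init__(self) -> None:
        for name in ("extsize", "local_background_span", "exclusion_span",
                     "min_junctions", "count_window", "min_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    count: int
    p_value: float
    q_value: float


@dataclass(frozen=True)
class TargetMatch:
    chrom: str
    start: int
    strand: str
    matched_seq: str
    mismatches: int
    pam_ok: bool
    presumed_cut: int


@dataclass
class Hotspot:
    chrom: str
    start: int
    end: int
    presumed_cut: int
    junction_count: int
    match: TargetMatch
    replicate_support: int
    balance_p: float = 1.0
    intensity: Optional[float] = None


def _exclude_bait(
    junctions: Sequence[tuple[str, int, str]],
    bait: Optional[BaitConfig],
    span: int,
) -> list[tuple[str, int, str]]:
    if bait is None:
        return list(junctions)
    return [
        j for j in junctions
        if not (j[0] == bait.chrom and abs(j[1] - bait.cut_pos) <= span)
    ]


def call_enriched_regions(
    junctions: Sequence[tuple[str, int, str]],
    genome_sizes: Mapping[str, int],
    params: PeakParams = PeakParams(),
    bait: Optional[BaitConfig] = None,
) -> list[CandidateRegion]:
    """Find junction clusters enriched over a local Poisson background.

    ``junctions`` are deduplicated (chrom, coord, strand) triples. Each
    junction is extended to ``extsize``; overlapping extensions merge
    into one candidate. The candidate's junction count k is tested with
    p = P(Poisson(lambda_local * span) >= k) where lambda_local is the
    per-bp junction rate, the maximum of the genome-wide rate and the
    rate within ``local_background_span`` around the candidate.
    Benjamini-Hochberg q-values use m = total genome length / extsize as
    the number of tests; candidates with q <= ``q_threshold`` are
    returned, never overlapping the bait exclusion zone.
    """
    kept = _exclude_bait(junctions, bait, params.exclusion_span)
    if not kept:
        return []
    genome_len = sum(genome_sizes.values())
    rate_global = len(kept) / genome_len
    half = params.extsize // 2
    by_chrom: dict[str, list[int]] = {}
    for chrom, coord, _ in kept:
        by_chrom.setdefault(chrom, []).append(coord)
    candidates: list[CandidateRegion] = []
    for chrom in sorted(by_chrom):
        coords = np.sort(np.array(by_chrom[chrom]))
        chrom_len = genome_sizes[chrom]
        # merge junctions whose +/- extsize/2 extensions overlap
        breaks = np.nonzero(np.diff(coords) > params.extsize)[0] + 1
        for block in np.split(coords, breaks):
            start = max(0, int(block[0]) - half)
            end = min(chrom_len, int(block[-1]) + half)
            span = end - start
            k = len(block)
            center = (start + end) // 2
            loc_lo = center - params.local_background_span // 2
            loc_hi = center + params.local_background_span // 2
            loc_span = min(loc_hi, chrom_len) - max(loc_lo, 0)
            n_local = int(np.searchsorted(coords, loc_hi) - np.searchsorted(coords, loc_lo))
            rate_local = n_local / loc_span if loc_span > 0 else 0.0
            lam = max(rate_global, rate_local) * span
            p = float(sps.poisson.sf(k - 1, lam))
            candidates.append(CandidateRegion(chrom, start, end, k, p, 1.0))
    m_tests = max(1, int(np.ceil(genome_len / params.extsize)))
    _bh_adjust(candidates, m_tests)
    out = [c for c in candidates if c.q_value <= params.q_threshold]
    out.sort(key=lambda c: (c.chrom, c.start))
    return out


def _bh_adjust(candidates: list[CandidateRegion], m_tests: int) -> None:
    """Benjamini-Hochberg over ``m_tests`` implicit tests; the untested
    windows all have p = 1 and rank last, so observed candidates keep
    their rank among themselves."""
    order = sorted(range(len(candidates)), key=lambda i: candidates[i].p_value)
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = len(order) - rank_from_end
        q = candidates[idx].p_value * m_tests / rank
        running = min(running, q)
        candidates[idx].q_value = running


def _matches_pam(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        base in IUPAC.get(code, "") for base, code in zip(seq, pattern)
    )


def find_cryptic_site(
    genome: "SequenceSource",
    chrom: str,
    start: int,
    end: int,
    guide_seq: str,
    params: PeakParams = PeakParams(),
) -> Optional[TargetMatch]:
    """Best target-similar 20-mer + PAM inside an interval (+/- slop).

    Scans both strands minimizing protospacer mismatches against
    ``guide_seq``. A site is accepted when mismatches <= max and the PAM
    matches one of the configured patterns, or when the mismatch count
    is at least 2 below the maximum regardless of PAM. The presumed cut
    lies 3 bp 5' of the PAM (between protospacer positions 17 and 18).
    Ties prefer an intact PAM, then the leftmost plus-strand site.
    """
    glen = len(guide_seq)
    plen = len(params.pam_patterns[0]) if params.pam_patterns else 3
    site_len = glen + plen
    lo = max(0, start - params.cryptic_slop - site_len)
    hi = min(genome.chrom_length(chrom), end + params.cryptic_slop + site_len)
    if hi - lo < site_len:
        return None
    seq = genome.fetch(chrom, lo, hi).upper()
    best: Optional[TargetMatch] = None
    best_key: tuple = ()
    for i in range(len(seq) - site_len + 1):
        window = seq[i : i + site_len]
        for strand in "+-":
            s = window if strand == "+" else revcomp(window)
            proto, pam = s[:glen], s[glen:]
            mm = sum(a != b for a, b in zip(proto, guide_seq))
            if mm > params.max_mismatches:
                continue
            pam_ok = any(_matches_pam(pam, pat) for pat in params.pam_patterns)
            if not (pam_ok or mm <= params.max_mismatches - 2):
                continue
            if strand == "+":
                cut = lo + i + glen - 3
            else:
                cut = lo + i + plen + 3
            key = (mm, not pam_ok, 0 if strand == "+" else 1, i)
            if best is None or key < best_key:
                best = TargetMatch(chrom, lo + i, strand, s, mm, pam_ok, cut)
                best_key = key
    return best


def _count_near(
    junctions: Sequence[tuple[str, int, str]], chrom: str, cut: int, window: int
) -> list[tuple[str, int, str]]:
    return [j for j in junctions if j[0] == chrom and abs(j[1] - cut) <= window]


def filter_and_merge(
    candidates_per_replicate: Sequence[Sequence[CandidateRegion]],
    junctions_per_replicate: Sequence[Sequence[tuple[str, int, str]]],
    genome: "SequenceSource",
    guide_seq: str,
    params: PeakParams = PeakParams(),
    require_replicates: bool = True,
) -> list[Hotspot]:
    """Merge candidates across replicates and apply the hotspot filters.

    Candidates lacking a cryptic target-like site are dropped. The rest
    are represented by their presumed cut extended by ``count_window``;
    overlapping extensions merge across replicates. A merged site is a
    hotspot iff it is supported by at least ``min_replicates`` replicate
    libraries (unless ``require_replicates`` is False) and the pooled
    junction count within ``count_window`` of the presumed cut reaches
    ``min_junctions``.
    """
    if require_replicates and len(candidates_per_replicate) < params.min_replicates:
        raise ValueError(
            f"need at least {params.min_replicates} replicates "
            f"(got {len(candidates_per_replicate)}); pass require_replicates=False to override"
        )
    entries = []  # (chrom, ext_start, ext_end, replicate, match)
    for rep, cands in enumerate(candidates_per_replicate):
        for cand in cands:
            match = find_cryptic_site(genome, cand.chrom, cand.start, cand.end, guide_seq, params)
            if match is None:
                continue
            entries.append(
                (
                    cand.chrom,
                    match.presumed_cut - params.count_window,
                    match.presumed_cut + params.count_window,
                    rep,
                    match,
                )
            )
    entries.sort(key=lambda e: (e[0], e[1], e[2], e[3]))
    pooled = [j for reps in junctions_per_replicate for j in reps]
    hotspots: list[Hotspot] = []
    i = 0
    while i < len(entries):
        chrom, lo, hi = entries[i][0], entries[i][1], entries[i][2]
        members = [entries[i]]
        j = i + 1
        while j < len(entries) and entries[j][0] == chrom and entries[j][1] < hi:
            hi = max(hi, entries[j][2])
            members.append(entries[j])
            j += 1
        i = j
        support = len({m[3] for m in members})
        match = min((m[4] for m in members), key=lambda t: (t.mismatches, not t.pam_ok, t.start))
        near = _count_near(pooled, chrom, match.presumed_cut, params.count_window)
        if require_replicates and support < params.min_replicates:
            continue
        if len(near) < params.min_junctions:
            continue
        hotspots.append(
            Hotspot(
                chrom=chrom,
                start=max(0, lo),
                end=hi,
                presumed_cut=match.presumed_cut,
                junction_count=len(near),
                match=match,
                replicate_support=support,
                balance_p=directional_balance([s for _, _, s in near]),
            )
        )
    hotspots.sort(key=lambda h: (h.chrom, h.start))
    return hotspots


def hotspot_intensity(junction_count: int, sample, control) -> float:
    """Junctions per 100,000 control-subtracted editing events.

    ``sample`` and ``control`` are :class:`~breaktrace.quantify.LibraryStats`;
    the denominator is (I_s - I_c) + (T_s - T_c).
    """
    denom = (sample.I - control.I) + (sample.T - control.T)
    if denom <= 0:
        raise ValueError("control-subtracted editing-event count must be positive")
    return junction_count / denom * 100_000


def directional_balance(strands: Sequence[str]) -> float:
    """Two-sided exact binomial p-value for +/- junction orientation balance.

    A genuine cut yields junctions in both orientations around the break;
    a skewed distribution suggests an artifact. Reported as an
    annotation, not used as a hard filter.
    """
    n = len(strands)
    if n == 0:
        raise ValueError("no junctions to test")
    k = sum(1 for s in strands if s == "+")
    return float(sps.binomtest(k, n, 0.5).pvalue)


class SequenceSource:
    """Minimal genome-sequence interface used by the cryptic-site scan."""

    def fetch(self, chrom: str, start: int, end: int) -> str:  # pragma: no cover
        raise NotImplementedError

    def chrom_length(self, chrom: str) -> int:  # pragma: no cover
        raise NotImplementedError
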