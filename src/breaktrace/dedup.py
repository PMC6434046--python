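"""PCR-duplicate removal by barcode clustering.

Molecules are first grouped by junction signature (chromosome, strand
and coordinate within a small positional tolerance); within each group,
barcodes within an edit distance threshold (default Levenshtein <= 2)
are linked and connected components collapse to one molecule each.

``N`` in a barcode matches nothing — it costs one edit against any
symbol, including another ``N`` — so reads with uncalled barcode bases
are retained without ever driving a merge on their own.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .junctions import JunctionCall

__all__ = [
    "MoleculeKey",
    "barcode_distance",
    "cluster_barcodes",
    "dedupe",
    "DedupReport",
]


@dataclass(frozen=True)
class MoleculeKey:
    rmb: str
    chrom: str
    coord: int
    strand: str
    bait_end: int


def _sym_eq(a: str, b: str) -> bool:
    return a == b and a != "N"


def barcode_distance(a: str, b: str, metric: str = "levenshtein", cap: int | None = None) -> int:
    """Edit distance between two barcodes under the N-matches-nothing rule.

    With ``cap`` set, any distance above it is reported as ``cap + 1``
    (banded computation for the Levenshtein metric).
    """
    if metric == "hamming":
        if len(a) != len(b):
            raise ValueError("hamming metric requires equal-length barcodes")
        d = sum(not _sym_eq(x, y) for x, y in zip(a, b))
        return d if cap is None or d <= cap else cap + 1
    if metric != "levenshtein":
        raise ValueError(f"unknown barcode metric: {metric!r}")
    n, m = len(a), len(b)
    if cap is not None and abs(n - m) > cap:
        return cap + 1
    band = cap if cap is not None else n + m
    inf = band + 1
    prev = [j if j <= band else inf for j in range(m + 1)]
    for i in range(1, n + 1):
        lo = max(1, i - band)
        hi = min(m, i + band)
        cur = [inf] * (m + 1)
        if lo == 1:
            cur[0] = i if i <= band else inf
        ai = a[i - 1]
        best = cur[0]
        for j in range(lo, hi + 1):
            cost = 0 if (ai == b[j - 1] and ai != "N") else 1
            d = prev[j - 1] + cost
            if prev[j] + 1 < d:
                d = prev[j] + 1
            if cur[j - 1] + 1 < d:
                d = cur[j - 1] + 1
            cur[j] = d if d <= band else inf
            if d < best:
                best = d
        if cap is not None and best > cap:
            return cap + 1
        prev = cur
    d = prev[m]
    return d if cap is None or d <= cap else cap + 1


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _deletion_variants(s: str, max_del: int) -> set[str]:
    out = {s}
    frontier = {s}
    for _ in range(max_del):
        nxt = set()
        for v in frontier:
            for i in range(len(v)):
                nxt.add(v[:i] + v[i + 1 :])
        out |= nxt
        frontier = nxt
    return out


def _candidate_pairs(barcodes: Sequence[str], max_edit: int) -> Iterable[tuple[int, int]]:
    """Pairs possibly within ``max_edit`` edits, by symmetric deletion.

    Two strings within Levenshtein distance d share at least one common
    subsequence obtainable by at most d deletions from each, so bucketing
    every <=``max_edit``-deletion variant finds all close pairs; members
    of a bucket are then verified with the real distance.
    """
    buckets: dict[str, list[int]] = defaultdict(list)
    for idx, bc in enumerate(barcodes):
        for v in _deletion_variants(bc, max_edit):
            buckets[v].append(idx)
    seen: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pair = (members[i], members[j]) if members[i] < members[j] else (members[j], members[i])
                if pair not in seen:
                    seen.add(pair)
                    yield pair


def cluster_barcodes(
    barcodes: Sequence[str],
    max_edit: int = 2,
    metric: str = "levenshtein",
) -> list[list[int]]:
    """Connected components under pairwise edit distance <= ``max_edit``.

    Returns clusters as lists of input indices; identical barcodes are
    always co-clustered. Clusters are ordered by first appearance.
    """
    uniq: dict[str, list[int]] = defaultdict(list)
    for i, bc in enumerate(barcodes):
        uniq[bc].append(i)
    reps = list(uniq)
    uf = _UnionFind(len(reps))
    if len(reps) <= 64:
        pairs: Iterable[tuple[int, int]] = (
            (i, j) for i in range(len(reps)) for j in range(i + 1, len(reps))
        )
    else:
        pairs = _candidate_pairs(reps, max_edit)
    for i, j in pairs:
        if barcode_distance(reps[i], reps[j], metric, cap=max_edit) <= max_edit:
            uf.union(i, j)
    comps: dict[int, list[int]] = defaultdict(list)
    for k, rep in enumerate(reps):
        comps[uf.find(k)].extend(uniq[rep])
    clusters = [sorted(members) for members in comps.values()]
    clusters.sort(key=lambda c: c[0])
    return clusters


@dataclass
class DedupReport:
    n_input: int = 0
    n_unique: int = 0
    cluster_size_hist: Counter = field(default_factory=Counter)

    @property
    def duplication_rate(self) -> float:
        return self.n_input / self.n_unique if self.n_unique else 0.0


def _junction_signature(call: JunctionCall, bait_chrom: str, bait_strand: str) -> tuple[str, str, int]:
    if call.prey is not None:
        return (call.prey.chrom, call.prey.strand, call.prey.coord)
    return (bait_chrom, bait_strand, call.bait_end)


def dedupe(
    calls: Sequence[JunctionCall],
    bait_chrom: str,
    bait_strand: str,
    max_edit: int = 2,
    pos_tolerance: int = 2,
    metric: str = "levenshtein",
) -> tuple[list[JunctionCall], DedupReport]:
    """Collapse PCR duplicates; one representative call per molecule.

    Calls are binned by (chromosome, strand), chained into positional
    groups whose consecutive junction coordinates differ by at most
    ``pos_tolerance``, and barcode-clustered within each group. The
    representative of a cluster is a call carrying its most frequent
    barcode (ties broken lexicographically). Output order is
    deterministic: sorted by junction signature, then barcode.
    """
    report = DedupReport(n_input=len(calls))
    keyed = sorted(
        ((_junction_signature(c, bait_chrom, bait_strand), i) for i, c in enumerate(calls)),
        key=lambda t: (t[0], calls[t[1]].rmb),
    )
    unique: list[JunctionCall] = []
    group: list[int] = []

    def flush(group_idx: list[int]) -> None:
        barcodes = [calls[i].rmb for i in group_idx]
        for cluster in cluster_barcodes(barcodes, max_edit=max_edit, metric=metric):
            counts = Counter(barcodes[k] for k in cluster)
            top = max(counts.items(), key=lambda kv: (kv[1], [-ord(ch) for ch in kv[0]]))[0]
            rep_idx = next(group_idx[k] for k in cluster if barcodes[k] == top)
            unique.append(calls[rep_idx])
            report.cluster_size_hist[len(cluster)] += 1

    prev_sig: Optional[tuple[str, str, int]] = None
    for sig, idx in keyed:
        if group and (
            sig[0] != prev_sig[0] or sig[1] != prev_sig[1] or sig[2] - prev_sig[2] > pos_tolerance
        ):
            flush(group)
            group = []
        group.append(idx)
        prev_sig = sig
    if group:
        flush(group)
    report.n_unique = len(unique)
    return unique, report
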