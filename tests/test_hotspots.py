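import math

import numpy as np
import pytest

from breaktrace.genome import Genome
from breaktrace.hotspots import (
    PeakParams,
    call_enriched_regions,
    directional_balance,
    filter_and_merge,
    find_cryptic_site,
    hotspot_intensity,
    revcomp,
)
from breaktrace.quantify import LibraryStats
from breaktrace.simulate import OffTargetSpec, SimSpec, make_genome

from conftest import GUIDE

# ---- independent Poisson-tail + BH oracle ---------------------------


def oracle_candidates(junction_coords, chrom_len, extsize=50, llocal=10_000_000):
    """Recompute candidate p/q-values from first principles (single
    chromosome): merge junctions closer than extsize, Poisson upper tail
    by direct term summation, Benjamini-Hochberg over genome/extsize
    implicit tests."""
    coords = sorted(junction_coords)
    blocks = []
    cur = [coords[0]]
    for c in coords[1:]:
        if c - cur[-1] > extsize:
            blocks.append(cur)
            cur = []
        cur.append(c)
    blocks.append(cur)
    rate_global = len(coords) / chrom_len

    def poisson_tail(k, lam):  # P(X >= k), direct term summation
        if k <= 0:
            return 1.0
        term = math.exp(-lam)
        for i in range(1, k + 1):
            term *= lam / i
        total, i = 0.0, k
        while term > 0.0 and i < k + 1000:
            total += term
            i += 1
            term *= lam / i
        return total

    results = []
    for block in blocks:
        start = max(0, block[0] - extsize // 2)
        end = min(chrom_len, block[-1] + extsize // 2)
        center = (start + end) // 2
        lo, hi = center - llocal // 2, center + llocal // 2
        n_local = sum(1 for c in coords if lo <= c < hi)
        span = min(hi, chrom_len) - max(lo, 0)
        lam = max(rate_global, n_local / span) * (end - start)
        results.append([start, end, len(block), poisson_tail(len(block), lam), 1.0])
    m = math.ceil(chrom_len / extsize)
    order = sorted(range(len(results)), key=lambda i: results[i][3])
    running = 1.0
    for back, idx in enumerate(reversed(order)):
        rank = len(order) - back
        running = min(running, results[idx][3] * m / rank)
        results[idx][4] = running
    return results


class TestCallEnrichedRegions:
    def _toy(self, seed=0):
        rng = np.random.default_rng(seed)
        cluster = [2_000_000 + int(x) for x in rng.integers(0, 100, 30)]
        background = [int(x) for x in rng.integers(0, 10_000_000, 30)]
        return cluster, background

    def test_cluster_found_background_rejected(self):
        cluster, background = self._toy()
        juncs = [("chr1", c, "+") for c in cluster + background]
        cands = call_enriched_regions(juncs, {"chr1": 10_000_000})
        assert len(cands) == 1
        assert cands[0].start <= min(cluster) and cands[0].end >= max(cluster)
        assert cands[0].count >= 30

    def test_qvalues_match_oracle(self):
        cluster, background = self._toy(3)
        coords = cluster + background
        juncs = [("chr1", c, "+") for c in coords]
        params = PeakParams(q_threshold=1.0)
        cands = call_enriched_regions(juncs, {"chr1": 10_000_000}, params)
        expected = oracle_candidates(coords, 10_000_000)
        assert len(cands) == len(expected)
        for cand, (start, end, count, p, q) in zip(
            sorted(cands, key=lambda c: c.start), sorted(expected)
        ):
            assert (cand.start, cand.end, cand.count) == (start, end, count)
            assert cand.p_value == pytest.approx(p, rel=1e-9, abs=1e-300)
            assert cand.q_value == pytest.approx(q, rel=1e-9, abs=1e-300)

    def test_uniform_background_mostly_silent(self):
        silent = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            juncs = [("chr1", int(x), "+") for x in rng.integers(0, 50_000_000, 500)]
            cands = call_enriched_regions(juncs, {"chr1": 50_000_000})
            silent += not cands
        assert silent >= 19

    def test_bait_exclusion(self, bait):
        cluster = [("chr1", bait.cut_pos + 100_000 + i, "+") for i in range(30)]
        cands = call_enriched_regions(cluster, {"chr1": 10_000_000}, bait=bait)
        assert cands == []

    def test_empty_input(self):
        assert call_enriched_regions([], {"chr1": 1_000_000}) == []

    def test_q_threshold_monotonicity(self):
        cluster, background = self._toy(5)
        juncs = [("chr1", c, "+") for c in cluster + background]
        counts = []
        for q in (1.0, 0.5, 0.05, 1e-6, 1e-30):
            cands = call_enriched_regions(juncs, {"chr1": 10_000_000}, PeakParams(q_threshold=q))
            counts.append(len(cands))
        assert counts == sorted(counts, reverse=True)


@pytest.fixture(scope="module")
def implanted():
    spec = SimSpec(
        genome_sizes={"chr1": 200_000},
        seed=13,
        guide_seq=GUIDE,
        bait_chrom="chr1",
        bait_cut_pos=50_000,
        mixture={"germline": 1.0},
        offtargets=(
            OffTargetSpec("chr1", 120_000, 3, "NGG", 1.0),
            OffTargetSpec("chr1", 160_000, 0, "none", 1.0),
        ),
    )
    genome, _ = make_genome(spec)
    return genome


@pytest.fixture(scope="module")
def merge_genome():
    spec = SimSpec(
        genome_sizes={"chr1": 5_000_000},
        seed=21,
        guide_seq=GUIDE,
        bait_chrom="chr1",
        bait_cut_pos=2_500_000,
        mixture={"germline": 1.0},
        offtargets=(
            OffTargetSpec("chr1", 1_000_000, 2, "NGG", 1.0),
            OffTargetSpec("chr1", 4_000_000, 3, "NAG", 1.0),
        ),
    )
    genome, _ = make_genome(spec)
    return genome


class TestFindCrypticSite:
    def test_on_target_exact(self, implanted):
        m = find_cryptic_site(implanted, "chr1", 49_900, 50_100, GUIDE)
        assert m is not None
        assert m.mismatches == 0 and m.pam_ok
        assert m.presumed_cut == 50_000

    def test_three_mismatch_ngg(self, implanted):
        m = find_cryptic_site(implanted, "chr1", 119_900, 120_100, GUIDE)
        assert m is not None
        assert m.mismatches == 3 and m.pam_ok
        assert m.presumed_cut == 120_000

    def test_pamless_perfect_match_found_via_relaxation(self, implanted):
        # 0 mismatches <= max_mm - 2, so a broken PAM is tolerated
        m = find_cryptic_site(implanted, "chr1", 159_900, 160_100, GUIDE)
        assert m is not None and m.mismatches == 0

    def test_random_region_none(self, implanted):
        # oracle: exhaustive scan confirms no <=6-mismatch site exists
        start, end = 10_000, 10_400
        seq = implanted.fetch("chr1", start - 73, end + 73)
        best = 99
        for i in range(len(seq) - 23 + 1):
            for s in (seq[i : i + 23], revcomp(seq[i : i + 23])):
                best = min(best, sum(a != b for a, b in zip(s[:20], GUIDE)))
        assert best > 6, "test region accidentally contains a similar site"
        assert find_cryptic_site(implanted, "chr1", start, end, GUIDE) is None

    def test_minus_strand_match(self):
        flank = "T" * 60
        site = GUIDE + "TGG"
        seq = flank + revcomp(site) + flank
        genome = Genome.from_sequences({"c": seq})
        m = find_cryptic_site(genome, "c", 55, 95, GUIDE, PeakParams(cryptic_slop=10))
        assert m is not None and m.strand == "-" and m.mismatches == 0
        # plus-strand cut sits 17 bases into the protospacer; mirrored here
        assert m.presumed_cut == 60 + 3 + 3


class TestFilterAndMerge:
    def _reps(self, site_counts):
        """site_counts: list of per-replicate {cut: n}."""
        reps = []
        for rep_sites in site_counts:
            juncs = []
            for cut, n in rep_sites.items():
                juncs.extend(("chr1", cut + i - n // 2, "+" if i % 2 else "-") for i in range(n))
            reps.append(juncs)
        return reps

    def test_recurrent_site_kept_with_pooled_count(self, merge_genome):
        reps = self._reps([{1_000_000: 10}, {1_000_000: 5}, {1_000_000: 4}])
        cands = [call_enriched_regions(j, {"chr1": 5_000_000}) for j in reps]
        hits = filter_and_merge(cands, reps, merge_genome, GUIDE)
        assert len(hits) == 1
        assert hits[0].junction_count == 19
        assert hits[0].replicate_support == 3
        assert abs(hits[0].presumed_cut - 1_000_000) <= 2

    def test_single_replicate_site_removed(self, merge_genome):
        reps = self._reps([{1_000_000: 10, 4_000_000: 12}, {1_000_000: 5}, {1_000_000: 4}])
        cands = [call_enriched_regions(j, {"chr1": 5_000_000}) for j in reps]
        hits = filter_and_merge(cands, reps, merge_genome, GUIDE)
        assert [abs(h.presumed_cut - 1_000_000) <= 2 for h in hits] == [True]

    def test_below_min_junctions_removed(self, merge_genome):
        reps = self._reps([{4_000_000: 1}, {4_000_000: 1}, {}])
        # force candidates through by threshold so the junction filter decides
        params = PeakParams(q_threshold=1.0)
        cands = [call_enriched_regions(j, {"chr1": 5_000_000}, params) for j in reps]
        hits = filter_and_merge(cands, reps, merge_genome, GUIDE, params)
        assert hits == []

    def test_replicate_requirement_enforced(self, merge_genome):
        reps = self._reps([{1_000_000: 10}])
        cands = [call_enriched_regions(j, {"chr1": 5_000_000}) for j in reps]
        with pytest.raises(ValueError):
            filter_and_merge(cands, reps, merge_genome, GUIDE)
        hits = filter_and_merge(cands, reps, merge_genome, GUIDE, require_replicates=False)
        assert len(hits) == 1


class TestHotspotIntensity:
    def test_basic(self):
        sample = LibraryStats(G=0, I=30_000, T=11_000)
        control = LibraryStats(G=0, I=500, T=500)
        assert hotspot_intensity(20, sample, control) == pytest.approx(50.0)

    def test_zero_junctions(self):
        sample = LibraryStats(G=0, I=2, T=0)
        control = LibraryStats(G=0, I=0, T=0)
        assert hotspot_intensity(0, sample, control) == 0.0

    def test_equal_counts_error(self):
        s = LibraryStats(G=0, I=5, T=5)
        with pytest.raises(ValueError):
            hotspot_intensity(1, s, s)


class TestDirectionalBalance:
    def test_balanced(self):
        assert directional_balance(["+"] * 10 + ["-"] * 10) == pytest.approx(1.0)

    def test_fully_skewed(self):
        assert directional_balance(["+"] * 20) == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_single_junction_degenerate(self):
        assert directional_balance(["+"]) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            directional_balance([])
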