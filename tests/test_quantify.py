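import numpy as np
import pytest
from hypothesis import given, strategies as st

from breaktrace.junctions import JunctionCall, PreyLocus
from breaktrace.quantify import (
    EfficiencyResult,
    LibraryStats,
    editing_efficiency,
    junction_profile,
    resection_fraction,
    tabulate,
)


def call(category, subcategory, prey=None, bait_end=10_000, rmb="A" * 14):
    c = JunctionCall(rmb, bait_end, PreyLocus(*prey) if prey else None)
    c.category, c.subcategory = category, subcategory
    return c


class TestTabulate:
    def test_counts(self):
        calls = (
            [call("germline", "perfect")] * 6
            + [call("indel", "small_deletion")] * 3
            + [call("translocation", "background_translocation", prey=("chr2", 5, "+"))]
        )
        stats = tabulate(calls)
        assert (stats.G, stats.I, stats.T) == (6, 3, 1)
        assert stats.total == 10
        assert stats.subcounts["small_deletion"] == 3

    def test_empty(self):
        stats = tabulate([])
        assert (stats.G, stats.I, stats.T) == (0, 0, 0)

    def test_subcounts_sum_matches_categories(self):
        calls = [call("indel", s) for s in ("small_insertion", "small_deletion", "large_deletion")]
        stats = tabulate(calls)
        assert stats.I == sum(
            v for k, v in stats.subcounts.items()
            if k in ("small_insertion", "small_deletion", "insertion_plus_deletion",
                     "large_deletion", "inversion")
        )

    def test_unclassified_rejected(self):
        with pytest.raises(ValueError):
            tabulate([JunctionCall("A" * 14, 1, None)])

    def test_simulated_mixture_within_ci(self):
        # multinomial sampling sanity at n=10,000 (99% CI per category)
        rng = np.random.default_rng(0)
        p = {"germline": 0.60, "indel": 0.35, "translocation": 0.05}
        cats = rng.choice(list(p), size=10_000, p=list(p.values()))
        calls = [
            call(c, {"germline": "perfect", "indel": "small_deletion",
                     "translocation": "background_translocation"}[c],
                 prey=("chr2", 5, "+") if c == "translocation" else None)
            for c in cats
        ]
        stats = tabulate(calls)
        for cat, count in (("germline", stats.G), ("indel", stats.I), ("translocation", stats.T)):
            half = 2.576 * np.sqrt(p[cat] * (1 - p[cat]) / 10_000)
            assert abs(count / 10_000 - p[cat]) < half


class TestEditingEfficiency:
    def test_identical_libraries_zero(self):
        s = LibraryStats(G=70, I=20, T=10)
        assert editing_efficiency(s, s, te=0.5).efficiency == 0.0

    def test_basic_fraction(self):
        sample = LibraryStats(G=6, I=3, T=1)
        control = LibraryStats(G=10, I=0, T=0)
        assert editing_efficiency(sample, control, te=1.0).efficiency == pytest.approx(0.40)

    def test_reported_sample_composition(self):
        # indels 35.7% + translocation 2.7% of molecules -> raw fraction 38.4%
        sample = LibraryStats(G=61_600, I=35_700, T=2_700)
        control = LibraryStats(G=100_000, I=0, T=0)
        result = editing_efficiency(sample, control, te=1.0)
        assert result.raw_sample_fraction == pytest.approx(0.384, abs=1e-12)
        assert result.efficiency == pytest.approx(0.384, abs=1e-12)

    def test_te_divides(self):
        sample = LibraryStats(G=6, I=3, T=1)
        control = LibraryStats(G=10, I=0, T=0)
        assert editing_efficiency(sample, control, te=0.5).efficiency == pytest.approx(0.80)

    def test_control_above_sample_clamps_with_warning(self):
        sample = LibraryStats(G=99, I=1, T=0)
        control = LibraryStats(G=90, I=10, T=0)
        with pytest.warns(UserWarning):
            assert editing_efficiency(sample, control).efficiency == 0.0

    @pytest.mark.parametrize("te", [0.0, -0.2, 1.5])
    def test_invalid_te(self, te):
        s = LibraryStats(G=1, I=1, T=0)
        with pytest.raises(ValueError):
            editing_efficiency(s, s, te=te)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            editing_efficiency(LibraryStats(G=0, I=0, T=0), LibraryStats(G=1, I=0, T=0))

    @given(st.integers(1, 30), st.integers(0, 30), st.integers(0, 30), st.integers(2, 9))
    def test_scaling_invariance(self, g, i, t, k):
        import warnings as _warnings

        sample = LibraryStats(G=g, I=i, T=t)
        scaled = LibraryStats(G=g * k, I=i * k, T=t * k)
        control = LibraryStats(G=50, I=1, T=0)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # clamp warnings near zero
            a = editing_efficiency(sample, control).efficiency
            b = editing_efficiency(scaled, control).efficiency
        assert a == pytest.approx(b, rel=1e-12)


class TestJunctionProfile:
    def test_all_at_center(self):
        tracks = junction_profile([(5_000, "+")] * 9, center=5_000, window=1_000, binsize=50)
        assert tracks["all"].sum() == 9
        assert tracks["all"][1_000 // 50] == 9

    def test_outside_window_excluded(self):
        tracks = junction_profile([(10_000, "+")], center=5_000, window=1_000, binsize=50)
        assert tracks["all"].sum() == 0

    def test_empty(self):
        tracks = junction_profile([], center=0, window=500, binsize=50)
        assert tracks["all"].sum() == 0

    def test_orientation_split_sums(self):
        juncs = [(4_990, "+"), (5_010, "-"), (5_020, "-")]
        tracks = junction_profile(juncs, center=5_000, window=1_000, binsize=50)
        assert tracks["+"].sum() == 1 and tracks["-"].sum() == 2
        assert (tracks["+"] + tracks["-"]).sum() == tracks["all"].sum()

    def test_uniform_counts_within_poisson_bounds(self):
        rng = np.random.default_rng(1)
        juncs = [(int(x), "+") for x in rng.integers(0, 10_000, 5_000)]
        tracks = junction_profile(juncs, center=5_000, window=5_000, binsize=100)
        lam = 5_000 / 100  # expected per bin
        assert tracks["all"].sum() == len([j for j, _ in juncs if 0 <= j < 10_000])
        assert np.all(np.abs(tracks["all"] - lam) < 6 * np.sqrt(lam))

    def test_truncated_last_bin(self):
        tracks = junction_profile([(5_990, "+")], center=5_000, window=1_000, binsize=300)
        assert len(tracks["all"]) == -(-2_000 // 300)
        assert tracks["all"].sum() == 1


class TestResectionFraction:
    def _stats(self):
        return LibraryStats(G=0, I=9_000, T=1_000)

    def test_no_junctions_in_region(self, bait):
        assert resection_fraction(self._stats(), [], bait) == 0.0

    def test_basic_arithmetic(self, bait):
        calls = [call("indel", "large_deletion", prey=("chr1", 10_000 + 20_000, "+"))
                 for _ in range(5)]
        assert resection_fraction(self._stats(), calls, bait) == pytest.approx(5 / 10_000)

    def test_region_boundaries(self, bait):
        inside = call("indel", "large_deletion", prey=("chr1", 10_000 + 5_000, "+"))
        beyond = call("indel", "large_deletion", prey=("chr1", 10_000 + 50_001, "+"))
        below = call("indel", "large_deletion", prey=("chr1", 10_000 + 4_999, "+"))
        assert resection_fraction(self._stats(), [inside, beyond, below], bait) == pytest.approx(1 / 10_000)

    def test_orientation_filter(self, bait):
        flipped = call("indel", "inversion", prey=("chr1", 10_000 + 20_000, "-"))
        upstream = call("indel", "large_deletion", prey=("chr1", 10_000 - 20_000, "+"))
        assert resection_fraction(self._stats(), [flipped, upstream], bait) == 0.0


class TestResectionRecovery:
    def test_implanted_tail_mass_recovered_within_twofold(self):
        """0.05%-of-editing-events resection tail, measured from molecule
        truth at n=50,000 (junction calls built directly from truth, no
        read simulation needed for this closed loop)."""
        from breaktrace.simulate import make_genome, simulate_molecules
        from conftest import make_spec

        p_edit = 0.40
        tail = 0.0005 * p_edit  # 0.05% of editing events, as molecule mass
        mixture = {"germline": 0.60, "small_deletion": p_edit - tail, "resection": tail}
        spec = make_spec(mixture=mixture, n_molecules=50_000)
        genome, _ = make_genome(spec)
        truth, _ = simulate_molecules(spec, genome, np.random.default_rng(4))
        calls = []
        for t in truth:
            prey = (t.prey_chrom, t.prey_coord, t.prey_strand) if t.prey_chrom else None
            calls.append(call(t.category, t.subcategory, prey=prey))
        stats = tabulate(calls)
        frac = resection_fraction(stats, calls, spec.bait_config())
        assert 0.0005 / 2 <= frac <= 0.0005 * 2


class TestMixingAndTitration:
    """Light-weight versions of the mixing/titration properties; the full
    read-level versions run in the acceptance suite."""

    def test_indel_fraction_proportional_to_mixing(self):
        rng = np.random.default_rng(2)
        base_indel = 0.4
        fractions = []
        ratios = [0.0, 0.25, 0.5, 1.0]
        for p in ratios:
            n = 20_000
            cats = rng.random(n) < base_indel * p
            calls = [call("indel", "small_deletion") if c else call("germline", "perfect")
                     for c in cats]
            stats = tabulate(calls)
            fractions.append(stats.I / stats.total)
        slope, intercept = np.polyfit(ratios, fractions, 1)
        pred = np.polyval([slope, intercept], ratios)
        ss_res = np.sum((np.array(fractions) - pred) ** 2)
        ss_tot = np.sum((np.array(fractions) - np.mean(fractions)) ** 2)
        assert 1 - ss_res / ss_tot >= 0.99

    def test_titration_stability_under_subsampling(self):
        rng = np.random.default_rng(3)
        calls = [call("indel", "small_deletion") if rng.random() < 0.35 else call("germline", "perfect")
                 for _ in range(20_000)]
        full = tabulate(calls)
        full_frac = full.I / full.total
        for frac in (0.5, 0.25, 0.1):
            sub = [calls[i] for i in rng.choice(len(calls), int(frac * len(calls)), replace=False)]
            stats = tabulate(sub)
            observed = stats.I / stats.total
            se = np.sqrt(full_frac * (1 - full_frac) / stats.total)
            assert abs(observed - full_frac) < 4 * se
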