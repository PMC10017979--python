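"""Core-panel selection, cover instances and minimal discriminating sets."""

import itertools
import math

import numpy as np
import pytest

import snpfingerprint as sf
from snpfingerprint.panel import ExactSearchRefused, InfeasibleError

from conftest import tiny_panel


def brute_force_min_cover(ci, k=1):
    """Exhaustive-enumeration oracle: smallest subset size that k-covers
    every pair, or None if infeasible."""
    n = len(ci.marker_ids)
    for size in range(0, n + 1):
        for combo in itertools.combinations(range(n), size):
            counts = [0] * len(ci.pairs)
            for m in combo:
                mask = ci.cover_sets[m]
                for q in range(len(ci.pairs)):
                    if (mask >> q) & 1:
                        counts[q] += 1
            if all(c >= k for c in counts):
                return size
    return None


def random_instance(seed, n_markers=10, n_samples=8):
    rng = np.random.default_rng(seed)
    rows = {}
    gts = ["A/A", "A/G", "G/G"]
    for j in range(n_markers):
        rows[f"m{j}"] = [gts[rng.integers(0, 3)] for _ in range(n_samples)]
    return tiny_panel(rows)


class TestBuildCoverInstance:
    def test_single_marker_covers_unequal_pairs(self):
        p = tiny_panel({"m1": ["A/A", "A/G", "A/A"]})
        ci = sf.build_cover_instance(p)
        assert ci.pairs == [("s1", "s2"), ("s1", "s3"), ("s2", "s3")]
        assert ci.cover_sets == [0b101]  # pairs (s1,s2) and (s2,s3)

    def test_monomorphic_marker_covers_nothing(self):
        p = tiny_panel({"m1": ["A/A", "A/A", "A/A"]})
        ci = sf.build_cover_instance(p)
        assert ci.cover_sets == [0]

    def test_missing_never_distinguishes(self):
        p = tiny_panel({"m1": ["A/A", "./."]})
        ci = sf.build_cover_instance(p)
        assert ci.cover_sets == [0]

    def test_validation_tables_all_pairs_covered(self, combined_validation_panel):
        ci = sf.build_cover_instance(combined_validation_panel)
        assert len(ci.pairs) == 21
        assert ci.uncoverable_pairs(1) == []


class TestGreedy:
    def test_single_differing_marker(self):
        rows = {"m1": ["A/A", "A/A"], "m2": ["A/A", "G/G"], "m3": ["C/C", "C/C"]}
        ci = sf.build_cover_instance(tiny_panel(rows))
        assert sf.minimal_discriminating_set_greedy(ci) == ["m2"]

    def test_infeasible_at_k2_when_single_cover(self):
        rows = {"m1": ["A/A", "A/A"], "m2": ["A/A", "G/G"]}
        ci = sf.build_cover_instance(tiny_panel(rows))
        with pytest.raises(InfeasibleError):
            sf.minimal_discriminating_set_greedy(ci, k=2)

    def test_duplicate_samples_infeasible(self):
        rows = {"m1": ["A/A", "A/A"], "m2": ["C/T", "C/T"]}
        ci = sf.build_cover_instance(tiny_panel(rows))
        with pytest.raises(InfeasibleError) as e:
            sf.minimal_discriminating_set_greedy(ci)
        assert ("s1", "s2") in e.value.pairs

    @pytest.mark.parametrize("seed", range(20))
    def test_greedy_always_covers_and_meets_ln_bound(self, seed):
        p = random_instance(seed)
        ci = sf.build_cover_instance(p)
        if ci.uncoverable_pairs(1):
            pytest.skip("instance infeasible by construction")
        g = sf.minimal_discriminating_set_greedy(ci)
        assert ci.covers_all(g, 1)
        opt = brute_force_min_cover(ci)
        assert opt <= len(g) <= opt * (math.log(len(ci.pairs)) + 1)


class TestExact:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumeration(self, seed):
        p = random_instance(seed, n_markers=10, n_samples=6)
        ci = sf.build_cover_instance(p)
        opt = brute_force_min_cover(ci)
        if opt is None:
            with pytest.raises(InfeasibleError):
                sf.minimal_discriminating_set_exact(ci)
        else:
            exact = sf.minimal_discriminating_set_exact(ci)
            assert len(exact) == opt and ci.covers_all(exact, 1)

    def test_k2_multicover(self):
        p = random_instance(99, n_markers=12, n_samples=5)
        ci = sf.build_cover_instance(p)
        if ci.uncoverable_pairs(2):
            pytest.skip("instance infeasible at k=2")
        exact = sf.minimal_discriminating_set_exact(ci, k=2)
        assert ci.covers_all(exact, 2)
        assert len(exact) == brute_force_min_cover(ci, k=2)

    def test_never_beats_exact(self):
        for seed in range(5):
            p = random_instance(seed + 200)
            ci = sf.build_cover_instance(p)
            if ci.uncoverable_pairs(1):
                continue
            g = sf.minimal_discriminating_set_greedy(ci)
            e = sf.minimal_discriminating_set_exact(ci)
            assert len(e) <= len(g)

    def test_search_guard(self):
        panel, _ = sf.simulate_panel(sf.SimConfig(seed=1, n_markers=60))
        ci = sf.build_cover_instance(panel)
        with pytest.raises(ExactSearchRefused):
            sf.minimal_discriminating_set_exact(ci)

    def test_lexicographically_smallest_optimum(self):
        # m1 and m2 both singly cover the one pair; m1 precedes m2
        rows = {"m1": ["A/A", "G/G"], "m2": ["C/C", "T/T"]}
        ci = sf.build_cover_instance(tiny_panel(rows))
        assert sf.minimal_discriminating_set_exact(ci) == ["m1"]

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_in_samples(self, seed):
        # adding a sample never shrinks the exact minimal set
        full = random_instance(seed + 300, n_markers=9, n_samples=6)
        sub = full.subset_samples(full.sample_ids[:5])
        ci_sub = sf.build_cover_instance(sub)
        ci_full = sf.build_cover_instance(full)
        if ci_full.uncoverable_pairs(1) or ci_sub.uncoverable_pairs(1):
            pytest.skip("instance infeasible by construction")
        assert len(sf.minimal_discriminating_set_exact(ci_sub)) <= len(
            sf.minimal_discriminating_set_exact(ci_full)
        )


class TestPlantedRecovery:
    @pytest.mark.parametrize("size", [2, 3, 4, 5, 6])
    def test_exact_recovers_planted_size(self, size):
        cfg = sf.SimConfig(seed=size * 13, n_markers=20 + size * 5,
                           samples_per_subpop=(size + 4,), fst=(0.1,), hybrids=())
        panel, truth = sf.plant_minimal_set(cfg, size)
        assert len(truth.planted_set) == size
        ci = sf.build_cover_instance(panel)
        exact = sf.minimal_discriminating_set_exact(ci, size_cap=size + 2)
        assert len(exact) == size

    def test_planted_set_itself_distinguishes(self):
        cfg = sf.SimConfig(seed=5, n_markers=30, samples_per_subpop=(8,),
                           fst=(0.1,), hybrids=())
        panel, truth = sf.plant_minimal_set(cfg, 4)
        ci = sf.build_cover_instance(panel)
        assert ci.covers_all(truth.planted_set, 1)

    def test_infeasible_construction_rejected(self):
        cfg = sf.SimConfig(seed=1, n_markers=10, samples_per_subpop=(30,),
                           fst=(0.1,), hybrids=())
        with pytest.raises(ValueError):
            sf.plant_minimal_set(cfg, 2)  # 3^2 < 30 profiles impossible


@pytest.fixture(scope="module")
def informative_panel():
    cfg = sf.SimConfig(seed=21, n_markers=900,
                       ancestral_maf_range=(0.3, 0.5), missing_rate=0.01)
    panel, _ = sf.simulate_panel(cfg)
    return panel, sf.marker_stats(panel)


class TestSelectCorePanel:
    def test_equal_quota_over_nine_chromosomes(self, informative_panel):
        panel, stats = informative_panel
        fp = sf.select_core_panel(panel, stats, sf.PanelConfig(target_size=50))
        assert len(fp.marker_ids) >= 50
        from collections import Counter

        chroms = Counter(
            panel.markers[panel.marker_index(m)].chrom
            for m in fp.marker_ids[:50]
        )
        assert set(chroms.values()) <= {5, 6}

    def test_low_pic_markers_never_selected(self, informative_panel):
        panel, stats = informative_panel
        fp = sf.select_core_panel(panel, stats, sf.PanelConfig())
        by_id = {s.marker_id: s for s in stats}
        assert all(by_id[m].pic >= 0.30 for m in fp.marker_ids)

    def test_selected_set_distinguishes_all_pairs(self, informative_panel):
        panel, stats = informative_panel
        fp = sf.select_core_panel(panel, stats, sf.PanelConfig())
        ci = sf.build_cover_instance(panel, fp.marker_ids)
        assert ci.uncoverable_pairs(1) == []

    def test_clonal_duplicates_raise_with_pair_named(self, informative_panel):
        panel, stats = informative_panel
        dup = sf.GenotypePanel(
            panel.markers,
            panel.samples + [sf.SampleMeta(sample_id="CLONE")],
            np.concatenate([panel.calls, panel.calls[:1]], axis=0),
        )
        with pytest.raises(InfeasibleError) as e:
            sf.select_core_panel(dup, sf.marker_stats(dup), sf.PanelConfig())
        assert any("CLONE" in pair for pair in e.value.pairs)

    def test_impossible_pic_threshold(self, informative_panel):
        panel, stats = informative_panel
        with pytest.raises(InfeasibleError):
            sf.select_core_panel(panel, stats, sf.PanelConfig(min_pic=0.9))


class TestRenderFingerprint:
    def test_tsv_and_barcodes(self):
        p = tiny_panel({"m1": ["A/A", "A/G"], "m2": ["C/C", "T/T"]})
        tsv = sf.render_fingerprint(p, ["m1", "m2"], "tsv")
        assert tsv.count("\n") == 3  # header + 2 marker rows
        barcodes = sf.render_fingerprint(p, ["m1", "m2"], "iupac-string")
        assert "s1\tAC" in barcodes and "s2\tRT" in barcodes

    def test_table7_barcodes_distinct(self, table7):
        text = sf.render_fingerprint(table7, table7.marker_ids, "iupac-string")
        codes = [line.split("\t")[1] for line in text.strip().splitlines()]
        assert len(codes) == 3 and len(set(codes)) == 3
        assert all(len(c) == 15 for c in codes)

    def test_missing_renders_as_n_and_missing_category(self):
        p = tiny_panel({"m1": ["./.", "A/A"], "m2": ["C/C", "T/T"]})
        bar = sf.render_fingerprint(p, ["m1", "m2"], "iupac-string")
        assert "s1\tNC" in bar
        grid = sf.render_fingerprint(p, ["m1", "m2"], "category-grid")
        assert "MISSING" in grid

    def test_unknown_format_rejected(self, table7):
        with pytest.raises(ValueError):
            sf.render_fingerprint(table7, table7.marker_ids, "png")

    def test_nondistinguishing_subset_warns(self):
        p = tiny_panel({"m1": ["A/A", "A/A"], "m2": ["A/A", "G/G"]})
        with pytest.warns(UserWarning):
            sf.render_fingerprint(p, ["m1"], "tsv")
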