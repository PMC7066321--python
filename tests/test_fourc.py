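"""4C calling: primer selection, site assignment, Z-score windows, regions."""
import math

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from vpcontact import (
    SimConfig,
    WindowParams,
    annotate_genes,
    assign_sites,
    binarize,
    call_interactions,
    merge_sites_to_regions,
    overlap_replicates,
    select_primer_reads,
    simulate_4c_reads,
    window_zscore,
    zscore_from_counts,
)
from vpcontact.fourc import counts_from_positions
from vpcontact.io import read_bed


class TestPrimerSelection:
    def test_exact_prefix_kept_and_trimmed(self):
        captured, stats = select_primer_reads(["AACCGGTT", "TTTTGGTT"], "AACC")
        assert captured == ["GGTT"]
        assert stats == {"kept": 1, "total": 2}

    def test_mismatch_tolerance(self):
        captured, _ = select_primer_reads(["AACCGGTT"], "AACG", max_mismatches=1)
        assert captured == ["GGTT"]

    def test_empty_primer_rejected(self):
        with pytest.raises(ValueError):
            select_primer_reads(["ACGT"], "")

    def test_simulated_library_all_carry_primer(self, small_world, small_config):
        genome, rmap, _ = small_world
        config = replace(small_config, duplication_rate=0.3)
        reads, truth = simulate_4c_reads(genome, rmap, config)
        chrom, idx = truth.bait
        pos = int(rmap.sites[chrom][idx])
        primer = genome[chrom][pos - config.primer_length : pos]
        captured, stats = select_primer_reads(reads, primer)
        assert stats["kept"] == stats["total"] == len(reads)
        assert all(len(c) == config.read_length - config.primer_length for c in captured)


class TestSiteAssignment:
    def test_constructed_fragment_end_maps_to_its_site(self, small_world):
        genome, rmap, _ = small_world
        fs, fe = rmap.fragment_of_site("chrB", 7)
        captured = [genome["chrB"][fs : fs + 40]]
        counts, stats = assign_sites(captured, rmap, genome)
        assert counts["chrB"][7] == 1 and stats["assigned"] == 1

    def test_random_sequence_unassigned(self, small_world):
        genome, rmap, _ = small_world
        counts, stats = assign_sites(["X" * 40], rmap, genome)
        assert stats["unassigned"] == 1
        assert all(c.sum() == 0 for c in counts.values())

    def test_full_library_counts_equal_draw_log(self, small_world, small_config):
        genome, rmap, _ = small_world
        reads, truth = simulate_4c_reads(genome, rmap, small_config)
        chrom, idx = truth.bait
        pos = int(rmap.sites[chrom][idx])
        primer = genome[chrom][pos - small_config.primer_length : pos]
        captured, _ = select_primer_reads(reads, primer)
        counts, stats = assign_sites(captured, rmap, genome)
        assert stats["unassigned"] == 0
        for c in rmap.chroms:
            assert np.array_equal(counts[c], truth.draw_counts[c])

    def test_premapped_positions_path(self, small_world):
        _, rmap, _ = small_world
        pos = int(rmap.sites["chrA"][4])
        counts = counts_from_positions(rmap, [("chrA", pos), ("chrA", pos + 5)])
        assert counts["chrA"][4] == 2


def test_binarize_thresholds_at_one():
    track = binarize({"c": np.array([0, 1, 7, 0])})
    assert track.indicator["c"].tolist() == [0, 1, 1, 0]
    assert track.counts["c"].tolist() == [0, 1, 7, 0]
    empty = binarize({"c": np.zeros(4, dtype=int)})
    assert empty.indicator["c"].sum() == 0
    with pytest.raises(ValueError):
        binarize({"c": np.array([-1, 0])})


class TestWindowZscore:
    def test_worked_example(self):
        """l_w=5, background sum 8 over L_W=20 -> mu=2; C=4 -> z~1.8257, p~0.034."""
        mu, z, p = zscore_from_counts(C=4, l_w=5, bg_sum=8, L_W=20)
        assert mu == pytest.approx(2.0)
        assert z == pytest.approx(2 / math.sqrt(2 * (1 - 2 / 5)), abs=1e-12)
        assert z == pytest.approx(1.8257, abs=1e-4)
        assert p == pytest.approx(0.0339, abs=1e-3)

    def test_centered_case_is_half(self):
        mu, z, p = zscore_from_counts(C=2, l_w=5, bg_sum=8, L_W=20)
        assert z == pytest.approx(0.0) and p == pytest.approx(0.5)

    def test_degenerate_windows_return_sentinel(self):
        for bg in (0, 20):  # mu = 0 and mu = l_w
            mu, z, p = zscore_from_counts(C=3, l_w=5, bg_sum=bg, L_W=20)
            assert math.isnan(z) and p == 1.0

    def test_track_path_agrees_with_counts_path(self):
        ind = np.zeros(41, dtype=int)
        ind[[18, 19, 21, 22, 5, 30, 35]] = 1
        params = WindowParams(l_w=5, L_W=21)
        stat = window_zscore(ind, 20, params)
        C = int(ind[18:23].sum())
        bg = int(ind[10:31].sum())
        mu, z, p = zscore_from_counts(C, 5, bg, 21)
        assert (stat.C, stat.mu) == (C, mu)
        assert stat.z == pytest.approx(z, abs=1e-12)
        assert stat.p == pytest.approx(p, abs=1e-12)

    @given(
        st.integers(2, 60),
        st.integers(0, 60),
        st.integers(0, 300),
    )
    def test_formula_equivalence_on_grid(self, l_w, C, bg_sum):
        """Independent arithmetic evaluation of the printed formula."""
        L_W = 5 * l_w
        bg_sum = min(bg_sum, L_W)
        mu, z, p = zscore_from_counts(C, l_w, bg_sum, L_W)
        mu_ref = bg_sum * l_w / L_W
        if 0 < mu_ref < l_w:
            z_ref = (C - mu_ref) / math.sqrt(mu_ref * (1 - mu_ref / l_w))
            assert abs(z - z_ref) < 1e-12
            assert abs(p - float(norm.sf(z_ref))) < 1e-12
        else:
            assert math.isnan(z) and p == 1.0

    def test_monotone_in_C_at_fixed_mu(self):
        zs = [zscore_from_counts(C, 10, 30, 100)[1] for C in range(11)]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_whole_chromosome_background(self):
        ind = np.zeros(50, dtype=int)
        ind[10:20] = 1
        stat = window_zscore(ind, 15, WindowParams(l_w=5, whole_chromosome=True))
        assert stat.mu == pytest.approx(10 * 5 / 50)

    def test_edge_truncation_rescales_expectation(self):
        ind = np.ones(30, dtype=int)
        ind[::3] = 0
        stat = window_zscore(ind, 0, WindowParams(l_w=11, L_W=21))
        # realized foreground = sites [0, 6), background = [0, 11)
        C = int(ind[:6].sum())
        mu, z, p = zscore_from_counts(C, 6, int(ind[:11].sum()), 11)
        assert stat.C == C and stat.mu == pytest.approx(mu)


class TestCallInteractions:
    def test_identical_track_identical_calls(self, small_world, small_config):
        genome, rmap, _ = small_world
        reads, truth = simulate_4c_reads(genome, rmap, small_config)
        counts, _ = assign_sites(
            select_primer_reads(reads, _primer(genome, rmap, truth, small_config))[0],
            rmap,
            genome,
        )
        track = binarize(counts)
        kw = dict(
            cis_params=WindowParams(11, 121), trans_params=WindowParams(15, whole_chromosome=True)
        )
        r1 = call_interactions(track, rmap, truth.bait, **kw)
        r2 = call_interactions(track, rmap, truth.bait, **kw)
        pd.testing.assert_frame_equal(r1.stats, r2.stats)

    def test_small_chromosome_skipped_with_warning(self, small_world, caplog):
        _, rmap, _ = small_world
        track = binarize(
            {"chrA": np.ones(rmap.n_sites("chrA"), dtype=int), "chrB": np.ones(3, dtype=int)}
        )
        rmap2 = rmap  # chrB indicator shorter than its site list is fine for the test
        result = call_interactions(
            track,
            rmap2,
            ("chrA", 5),
            cis_params=WindowParams(11, 121),
            trans_params=WindowParams(15, whole_chromosome=True),
        )
        assert "chrB" in result.skipped

    def test_exclusion_zone_never_flagged(self, small_world, small_config):
        genome, rmap, _ = small_world
        reads, truth = simulate_4c_reads(genome, rmap, small_config)
        counts, _ = assign_sites(
            select_primer_reads(reads, _primer(genome, rmap, truth, small_config))[0],
            rmap,
            genome,
        )
        result = call_interactions(
            binarize(counts),
            rmap,
            truth.bait,
            cis_params=WindowParams(11, 121),
            trans_params=WindowParams(15, whole_chromosome=True),
            exclusion_sites=10,
        )
        chrom, idx = truth.bait
        near = result.stats[
            (result.stats.chrom == chrom) & (np.abs(result.stats.site - idx) <= 10)
        ]
        assert not near["significant"].any()
        assert not near["evaluated"].any()


def _primer(genome, rmap, truth, config):
    chrom, idx = truth.bait
    pos = int(rmap.sites[chrom][idx])
    return genome[chrom][pos - config.primer_length : pos]


class TestRegionMerging:
    def brute_merge(self, idx, gap):
        """Oracle: greedy left-to-right grouping."""
        groups = []
        for k in sorted(idx):
            if groups and k - groups[-1][-1] <= gap + 1:
                groups[-1].append(k)
            else:
                groups.append([k])
        return [(g[0], g[-1], len(g)) for g in groups]

    def test_consecutive_sites_one_region(self, small_world):
        _, rmap, _ = small_world
        calls = merge_sites_to_regions({"chrA": np.array([5, 6, 7])}, rmap, max_gap_sites=0)
        assert len(calls) == 1 and calls[0].n_sites == 3

    def test_gap_parameter_boundary(self, small_world):
        _, rmap, _ = small_world
        one = merge_sites_to_regions({"chrA": np.array([5, 9])}, rmap, max_gap_sites=3)
        two = merge_sites_to_regions({"chrA": np.array([5, 9])}, rmap, max_gap_sites=2)
        assert len(one) == 1 and len(two) == 2

    def test_empty_input_empty_output(self, small_world):
        _, rmap, _ = small_world
        assert merge_sites_to_regions({}, rmap) == []

    @given(st.integers(0, 5000), st.integers(0, 4))
    def test_matches_brute_force_oracle(self, seed, gap):
        rng = np.random.default_rng(seed)
        idx = np.unique(rng.integers(0, 60, size=rng.integers(1, 25)))
        from vpcontact import digest as digest_fn, resolve_enzyme

        genome = {"c": ("A" * 30 + "GATC") * 70}
        rmap = digest_fn(genome, resolve_enzyme("DpnII"))
        calls = merge_sites_to_regions({"c": idx}, rmap, max_gap_sites=gap)
        oracle = self.brute_merge(idx.tolist(), gap)
        assert [(c.n_sites) for c in calls] == [n for _, _, n in oracle]
        for call, (first, last, _) in zip(calls, oracle):
            assert call.start == int(rmap.sites["c"][first])
            assert call.end == rmap.fragment_of_site("c", last)[1]

    def test_region_endpoints_on_site_coordinates(self, small_world):
        _, rmap, _ = small_world
        calls = merge_sites_to_regions({"chrA": np.array([3, 4, 10])}, rmap, max_gap_sites=1)
        site_coords = set(rmap.sites["chrA"].tolist()) | {rmap.chrom_lengths["chrA"]}
        for c in calls:
            assert c.start in site_coords and c.end in site_coords


class TestReplicateOverlap:
    def brute(self, r1, r2):
        out = set()
        for c1, s1, e1 in r1:
            for c2, s2, e2 in r2:
                if c1 == c2 and max(s1, s2) < min(e1, e2):
                    out.add((c1, max(s1, s2), min(e1, e2)))
        return sorted(out)

    def test_identical_lists_idempotent(self):
        regions = [("c", 10, 20), ("c", 30, 50)]
        assert overlap_replicates(regions, regions) == regions

    def test_disjoint_lists_empty(self):
        assert overlap_replicates([("c", 0, 10)], [("c", 10, 20)]) == []

    @given(st.integers(0, 3000))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def random_regions():
            starts = np.sort(rng.choice(200, size=rng.integers(1, 10), replace=False))
            out, prev = [], 0
            for s in starts.tolist():
                s = max(s, prev)
                e = s + int(rng.integers(1, 15))
                out.append(("c", s, e))
                prev = e  # non-overlapping within a replicate, like merged calls
            return out

        r1, r2 = random_regions(), random_regions()
        assert overlap_replicates(r1, r2) == self.brute(r1, r2)
        assert overlap_replicates(r2, r1) == self.brute(r1, r2)  # symmetric content


class TestGeneAnnotation:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])

    def test_gene_inside_region_reported(self):
        genes = self._genes([("c", 15, 18, "g1", "+")])
        per_region, n = annotate_genes([("c", 10, 20)], genes)
        assert per_region == [["g1"]] and n == 1

    def test_gene_spanning_two_regions_counted_once(self):
        genes = self._genes([("c", 0, 100, "g1", "+")])
        per_region, n = annotate_genes([("c", 10, 20), ("c", 50, 60)], genes)
        assert per_region == [["g1"], ["g1"]] and n == 1

    @given(st.integers(0, 3000))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        regions = [
            ("c", int(s), int(s + rng.integers(1, 20)))
            for s in rng.integers(0, 200, size=5)
        ]
        genes = self._genes(
            [
                ("c", int(s), int(s + rng.integers(1, 30)), f"g{i}", "+")
                for i, s in enumerate(rng.integers(0, 220, size=12))
            ]
        )
        per_region, n = annotate_genes(regions, genes)
        expected_unique = set()
        for (rc, rs, re), hits in zip(regions, per_region):
            oracle = [
                row["name"]
                for _, row in genes.iterrows()
                if row.chrom == rc and row.start < re and row.end > rs
            ]
            assert sorted(hits) == sorted(oracle)
            expected_unique.update(oracle)
        assert n == len(expected_unique)

    def test_malformed_bed_names_line(self, tmp_path):
        bad = tmp_path / "genes.bed"
        bad.write_text("c\t10\t20\tg1\nc\tten\t30\tg2\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(bad)


def test_duplication_invariance_of_calls(small_world, small_config):
    """Binarization makes calls identical across duplication rates."""
    genome, rmap, _ = small_world
    results = {}
    for rate in (0.0, 0.5):
        config = replace(small_config, duplication_rate=rate)
        reads, truth = simulate_4c_reads(genome, rmap, config)
        captured, _ = select_primer_reads(reads, _primer(genome, rmap, truth, config))
        counts, _ = assign_sites(captured, rmap, genome)
        results[rate] = call_interactions(
            binarize(counts),
            rmap,
            truth.bait,
            cis_params=WindowParams(11, 121),
            trans_params=WindowParams(15, whole_chromosome=True),
        )
    pd.testing.assert_frame_equal(results[0.0].stats, results[0.5].stats)
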