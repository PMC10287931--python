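import numpy as np
import pandas as pd
import pytest

from larpmap import site_calling as sc
from larpmap.formats_io import READ_COLUMNS

from _oracles import brute_force_call_sites, kernel_sum
from conftest import make_reads


def random_instance(rng, max_reads=50, n_chroms=2):
    rows = []
    n = int(rng.integers(1, max_reads + 1))
    for _ in range(n):
        chrom = f"c{rng.integers(n_chroms)}"
        strand = "+" if rng.random() < 0.8 else "-"
        start = int(rng.integers(0, 80))
        length = int(rng.integers(10, 41))
        k = int(rng.integers(0, 4))
        offs = tuple(sorted(set(int(x) for x in rng.integers(0, length, size=k))))
        rows.append((chrom, start, start + length, strand, offs))
    return rows


def site_tuples(sites):
    return sorted(
        (r.chrom, int(r.start), int(r.end), int(r.read_count), int(r.conversion_count),
         int(r.mode_location), r.strand)
        for r in sites.itertuples(index=False)
    )


class TestFilters:
    def test_min_length_filter(self):
        reads = make_reads([("c", 0, 12, "+", ()), ("c", 0, 13, "+", ()), ("c", 0, 14, "+", ())])
        kept = sc.filter_reads(reads, min_len=13)
        assert sorted(kept["end"] - kept["start"]) == [13, 14]

    def test_empty_input_empty_output(self):
        reads = make_reads([])
        assert len(sc.filter_reads(reads, 13)) == 0

    def test_min_len_one_is_identity(self):
        reads = make_reads([("c", 0, 5, "+", ()), ("c", 3, 30, "+", ())])
        pd.testing.assert_frame_equal(sc.filter_reads(reads, 1), reads)


class TestGrouping:
    def test_four_overlapping_reads_no_group(self):
        reads = make_reads([("c", i, i + 20, "+", ()) for i in range(4)])
        assert sc.group_reads(reads, min_group_reads=5) == []

    def test_five_overlapping_plus_disjoint_gives_one_group(self):
        rows = [("c", i, i + 20, "+", ()) for i in range(5)] + [("c", 500, 520, "+", ())]
        groups = sc.group_reads(make_reads(rows), min_group_reads=5)
        assert len(groups) == 1 and groups[0].n_reads == 5

    def test_strands_grouped_separately(self):
        rows = [("c", 0, 20, "+", ()) for _ in range(5)] + [("c", 0, 20, "-", ()) for _ in range(5)]
        groups = sc.group_reads(make_reads(rows), min_group_reads=5)
        assert len(groups) == 2
        assert {g.strand for g in groups} == {"+", "-"}

    def test_touching_reads_do_not_merge(self):
        # half-open intervals: [0,20) and [20,40) share no base
        rows = [("c", 0, 20, "+", ()) for _ in range(5)] + [("c", 20, 40, "+", ()) for _ in range(5)]
        groups = sc.group_reads(make_reads(rows), min_group_reads=5)
        assert len(groups) == 2


class TestDensities:
    def test_zero_conversions_zero_signal(self):
        groups = sc.group_reads(make_reads([("c", 0, 20, "+", ()) for _ in range(6)]))
        prof = sc.estimate_densities(groups[0])
        assert np.all(prof.signal == 0)
        defined = ~np.isnan(prof.ratio)
        assert np.all(prof.ratio[defined] == 0)

    def test_single_conversion_peaks_at_datum(self):
        groups = sc.group_reads(make_reads([("c", 0, 21, "+", (10,))] + [("c", 0, 21, "+", ())] * 5))
        prof = sc.estimate_densities(groups[0], bandwidth=0.5)
        assert sc.mode_location(prof) == 10

    def test_densities_match_brute_force_kernel_sums(self):
        rng = np.random.default_rng(11)
        rows = random_instance(rng, max_reads=20, n_chroms=1)
        groups = sc.group_reads(make_reads(rows), min_group_reads=1)
        for group in groups:
            prof = sc.estimate_densities(group, bandwidth=3.0)
            events = [p for r in group.reads.itertuples(index=False)
                      for p in ([r.start + o for o in r.conversions] if r.strand == "+"
                                else [r.end - 1 - o for o in r.conversions])]
            raw = np.array([kernel_sum(events, p, 3.0) for p in range(group.start, group.end)])
            expected = raw / raw.sum() if raw.sum() > 0 else raw
            np.testing.assert_allclose(prof.signal, expected, atol=1e-9)

    def test_bad_bandwidth_rejected(self):
        groups = sc.group_reads(make_reads([("c", 0, 20, "+", ()) for _ in range(5)]))
        with pytest.raises(ValueError):
            sc.estimate_densities(groups[0], bandwidth=0.0)


class TestModeLocation:
    def _profile(self, ratio, start=10):
        n = len(ratio)
        return sc.DensityProfile(
            "c", "+", start,
            signal=np.zeros(n), background=np.zeros(n),
            ratio=np.asarray(ratio, dtype=float), depth=np.full(n, 10),
        )

    def test_leftmost_max_tie_rule(self):
        assert sc.mode_location(self._profile([0.2, 0.9, 0.9, 0.5])) == 11

    def test_single_defined_position(self):
        assert sc.mode_location(self._profile([np.nan, 0.4, np.nan])) == 11

    def test_uniform_ratio_gives_leftmost(self):
        assert sc.mode_location(self._profile([0.5, 0.5, 0.5])) == 10

    def test_all_masked_is_error(self):
        with pytest.raises(ValueError, match="no defined ratio"):
            sc.mode_location(self._profile([np.nan, np.nan]))


class TestCallSites:
    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            rows = random_instance(rng)
            reads = make_reads(rows)
            mine = site_tuples(sc.call_sites_from_reads(reads, sc.SiteCallParams()))
            oracle = brute_force_call_sites(
                [dict(chrom=c, start=s, end=e, strand=st, conversions=conv)
                 for c, s, e, st, conv in rows]
            )
            assert mine == oracle

    def test_oracle_equivalence_with_sequence_background(self):
        rng = np.random.default_rng(5)
        seqs = {f"c{i}": "".join(rng.choice(list("ACGT"), size=150)) for i in range(2)}
        for _ in range(10):
            rows = random_instance(rng)
            reads = make_reads(rows)
            mine = site_tuples(sc.call_sites_from_reads(reads, sc.SiteCallParams(), seqs))
            oracle = brute_force_call_sites(
                [dict(chrom=c, start=s, end=e, strand=st, conversions=conv)
                 for c, s, e, st, conv in rows],
                sequences=seqs,
            )
            assert mine == oracle

    def test_added_conversion_read_preserves_existing_modes(self):
        """Adding a conversion-bearing read never removes an existing mode
        from the candidate-run set."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(30):
            rows = random_instance(rng, max_reads=30, n_chroms=1)
            reads = make_reads(rows)
            before = sc.call_sites_from_reads(reads, sc.SiteCallParams())
            if len(before) == 0:
                continue
            mode = int(before.iloc[0].mode_location)
            chrom, strand = before.iloc[0].chrom, before.iloc[0].strand
            extra = make_reads(rows + [(chrom, max(0, mode - 10), mode + 10, strand, (10,))])
            after_groups = sc.group_reads(sc.filter_reads(extra, 13), 5)
            runs = []
            for g in after_groups:
                if g.chrom != chrom or g.strand != strand:
                    continue
                prof = sc.estimate_densities(g)
                runs.extend(sc._candidate_runs(prof))
            assert any(s <= mode < e for s, e in runs)
            checked += 1
        assert checked >= 5

    def test_emitted_sites_satisfy_invariants(self, small_sim):
        _, _, _, _, reads = small_sim
        sites = sc.call_sites_from_reads(reads, sc.SiteCallParams())
        widths = sites["end"] - sites["start"]
        assert widths.between(11, 100).all()
        assert (sites["conversion_count"] >= 2).all()
        assert ((sites["mode_location"] >= sites["start"])
                & (sites["mode_location"] < sites["end"])).all()


class TestThresholdFixtures:
    """Constructed fixtures exercising each published filter exactly.

    The all-A sequence keeps the background density empty so run extents are
    fully predictable (signal > 0 everywhere within the group span).
    """

    SEQ = {"c": "A" * 200}

    def test_width_eleven_accepted_width_ten_impossible_after_mask(self):
        # five 13-nt reads staggered by 1: depth >=5 only on [4,13), a 9-nt
        # run -> rejected; identical unstaggered reads span 13 nt -> accepted
        staggered = make_reads([("c", i, i + 13, "+", (8 - i,)) for i in range(5)])
        sites = sc.call_sites_from_reads(staggered, sc.SiteCallParams(), self.SEQ)
        assert len(sites) == 0
        assert sites.attrs["filter_counts"]["too_narrow"] == 1
        aligned = make_reads(
            [("c", 0, 13, "+", (6,)), ("c", 0, 13, "+", (6,))] + [("c", 0, 13, "+", ())] * 3
        )
        sites = sc.call_sites_from_reads(aligned, sc.SiteCallParams(), self.SEQ)
        assert len(sites) == 1
        assert int(sites.iloc[0].end - sites.iloc[0].start) == 13

    def test_cluster_wider_than_100_rejected(self):
        reads = make_reads(
            [("c", 0, 150, "+", (75,)), ("c", 0, 150, "+", (75,))] + [("c", 0, 150, "+", ())] * 3
        )
        sites = sc.call_sites_from_reads(reads, sc.SiteCallParams(), self.SEQ)
        assert len(sites) == 0
        assert sites.attrs["filter_counts"]["too_wide"] == 1

    def test_single_conversion_rejected_two_accepted(self):
        one = make_reads([("c", 0, 20, "+", (6,))] + [("c", 0, 20, "+", ())] * 4)
        sites = sc.call_sites_from_reads(one, sc.SiteCallParams(), self.SEQ)
        assert len(sites) == 0
        assert sites.attrs["filter_counts"]["too_few_conversions"] == 1
        two = make_reads([("c", 0, 20, "+", (6,)), ("c", 0, 20, "+", (6,))] + [("c", 0, 20, "+", ())] * 3)
        assert len(sc.call_sites_from_reads(two, sc.SiteCallParams(), self.SEQ)) == 1

    def test_conversions_must_come_from_two_distinct_reads(self):
        one_read = make_reads([("c", 0, 20, "+", (6, 9))] + [("c", 0, 20, "+", ())] * 4)
        sites = sc.call_sites_from_reads(one_read, sc.SiteCallParams(), self.SEQ)
        assert len(sites) == 0
        assert sites.attrs["filter_counts"]["too_few_conv_reads"] == 1

    def test_short_read_discard_can_break_group_threshold(self):
        # 5 overlapping reads, one only 12 nt: length filter leaves 4 -> no group
        rows = [("c", 0, 12, "+", (6,))] + [("c", 0, 20, "+", (6,))] * 4
        sites = sc.call_sites_from_reads(make_reads(rows), sc.SiteCallParams(), self.SEQ)
        assert len(sites) == 0
        assert sites.attrs["filter_counts"]["groups"] == 0
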