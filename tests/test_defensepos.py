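"""Defense positioning, LT-region arithmetic, and headful-distance maps
against exhaustive per-base oracles."""

import numpy as np
import pandas as pd
import pytest

from ltscope.defensepos import (
    DefenseSystem,
    RegionLabel,
    count_defense_windows,
    defense_in_prophage_spot_fraction,
    headful_distance_map,
    headful_fraction_within,
    label_defense_vs_prophage,
    lt_region,
    midpoint,
)
from ltscope.prophagecls import ProphageCall


def system(start, end, genome="G", sid="d1"):
    return DefenseSystem(genome=genome, system_id=sid, system_name="x",
                         start=start, end=end)


class TestMidpoint:
    def test_plain_span(self):
        assert midpoint(system(1000, 3000)) == 2000

    def test_single_bp_span(self):
        assert midpoint(system(0, 1)) == 0

    def test_wrap_spanning_span_unwraps_then_reduces(self):
        assert midpoint(system(4_999_000, 5_001_000), genome_length=5_000_000) == 0

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            midpoint(system(10, 10))


def oriented_prophage(start, end, orientation, terl_span, genome="G"):
    """A prophage with synthetic gene ids; TerL coordinates supplied."""
    call = ProphageCall(genome, start, end, ("int", "terS", "terL", "x"),
                        int_gene="int", orientation=orientation,
                        terS_gene="terS", terL_gene="terL", terL_similarity=85.0,
                        pac_related=True)
    coords = {"terL": terl_span}
    return call, coords


class TestRegionLabels:
    GLEN = 1_000_000

    def test_between_terminase_and_end(self):
        call, coords = oriented_prophage(100_000, 140_000, "packaging_rightward",
                                         (115_000, 116_000))
        lab = label_defense_vs_prophage(system(117_500, 118_500), call, coords, self.GLEN)
        assert lab is RegionLabel.terminase_to_end

    def test_midpoint_exactly_at_terl_end_counts_as_after(self):
        call, coords = oriented_prophage(100_000, 140_000, "packaging_rightward",
                                         (115_000, 116_000))
        lab = label_defense_vs_prophage(system(115_500, 116_500), call, coords, self.GLEN)
        assert lab is RegionLabel.terminase_to_end

    def test_before_terminase(self):
        call, coords = oriented_prophage(100_000, 140_000, "packaging_rightward",
                                         (115_000, 116_000))
        lab = label_defense_vs_prophage(system(104_000, 106_000), call, coords, self.GLEN)
        assert lab is RegionLabel.int_to_terminase

    def test_downstream_and_upstream_windows(self):
        call, coords = oriented_prophage(100_000, 140_000, "packaging_rightward",
                                         (115_000, 116_000))
        assert label_defense_vs_prophage(
            system(149_000, 151_000), call, coords, self.GLEN
        ) is RegionLabel.downstream_window
        assert label_defense_vs_prophage(
            system(89_000, 91_000), call, coords, self.GLEN
        ) is RegionLabel.upstream_of_prophage
        assert label_defense_vs_prophage(
            system(400_000, 402_000), call, coords, self.GLEN
        ) is RegionLabel.chromosomal_far

    def test_leftward_prophage_mirrors_rightward(self):
        # same element, integrase at the right end: packaging runs leftward
        call, _ = oriented_prophage(100_000, 140_000, "packaging_leftward",
                                    (124_000, 125_000))
        coords = {"terL": (124_000, 125_000)}
        # midpoint between prophage start and TerL, on the packaged side
        lab = label_defense_vs_prophage(system(104_000, 106_000), call, coords, self.GLEN)
        assert lab is RegionLabel.terminase_to_end
        lab = label_defense_vs_prophage(system(130_000, 132_000), call, coords, self.GLEN)
        assert lab is RegionLabel.int_to_terminase
        # just left of the prophage = past its packaging end
        lab = label_defense_vs_prophage(system(89_000, 91_000), call, coords, self.GLEN)
        assert lab is RegionLabel.downstream_window

    def test_unoriented_prophage_rejected(self):
        call = ProphageCall("G", 0, 40_000, ("a",), orientation="unknown")
        with pytest.raises(ValueError, match="unknown orientation"):
            label_defense_vs_prophage(system(1000, 2000), call, {}, self.GLEN)

    def test_rotation_invariance_on_circular_genome(self):
        glen = 500_000
        for delta in (0, 123_000, 480_000):
            start = (100_000 + delta) % glen
            end = (140_000 + delta) % glen
            if end < start:
                end += glen  # unwrapped span convention
            call, coords = oriented_prophage(start, end, "packaging_rightward",
                                             ((115_000 + delta) % glen,
                                              (116_000 + delta) % glen))
            s = system((117_500 + delta) % glen, (118_500 + delta) % glen)
            if s.end < s.start:
                s = system(s.start, s.end + glen)
            lab = label_defense_vs_prophage(s, call, coords, glen)
            assert lab is RegionLabel.terminase_to_end


class TestWindowCounts:
    GLEN = {"G": 1_000_000}

    def _pac_prophage(self):
        return oriented_prophage(100_000, 140_000, "packaging_rightward",
                                 (115_000, 116_000))

    def test_defense_past_end_counted_in_pac_row(self):
        call, coords = self._pac_prophage()
        out = count_defense_windows([call], [system(149_500, 150_500)], coords, self.GLEN)
        hit = out[(out["region"] == "25kb-past-end") & (out["prophage_class"] == "pac")]
        assert int(hit["n_defense_systems"].iloc[0]) == 1
        assert out["n_defense_systems"].sum() == 1

    def test_defense_beyond_window_not_counted(self):
        call, coords = self._pac_prophage()
        out = count_defense_windows([call], [system(169_000, 171_000)], coords, self.GLEN)
        assert out["n_defense_systems"].sum() == 0

    def test_boundary_25001_bp_past_end_not_counted(self):
        call, coords = self._pac_prophage()
        # midpoint exactly 25,001 bp past the prophage end
        out = count_defense_windows([call], [system(165_000, 165_002)], coords, self.GLEN)
        assert out["n_defense_systems"].sum() == 0

    def test_counts_split_by_pac_class(self, pipeline_result, default_collection,
                                       gene_coords):
        """Post-terminase defenses were planted only in pac prophages."""
        _, _, truth = default_collection
        _, result = pipeline_result
        out = result.window_counts
        post = out[out["region"] == "terminase-to-end"]
        pac_n = int(post.loc[post["prophage_class"] == "pac", "n_defense_systems"].iloc[0])
        other_n = int(
            post.loc[post["prophage_class"] == "other", "n_defense_systems"].iloc[0]
        )
        n_planted_post = int(
            (truth.defenses["position"] == "post_terminase").sum()
        )
        assert pac_n >= n_planted_post
        assert other_n == 0


class TestLTRegion:
    def test_three_headfuls_rightward(self):
        r = lt_region(100_000, "rightward", 3, genome_length=1_000_000)
        assert r.span() == (100_000, 235_000)
        assert r.boundaries == [145_000, 190_000, 235_000]
        assert r.contains(234_999) and not r.contains(235_000)

    def test_leftward_clipped_on_linear_genome(self):
        r = lt_region(10_000, "leftward", 1, genome_length=100_000, circular=False)
        assert r.span() == (0, 10_000)
        assert r.truncated

    def test_wrap_on_circular_genome(self):
        r = lt_region(480_000, "rightward", 1, genome_length=500_000)
        assert r.contains(490_000) and r.contains(10_000) and not r.contains(30_000)

    def test_self_overlapping_region_rejected(self):
        with pytest.raises(ValueError, match="self-overlap"):
            lt_region(0, "rightward", 12, genome_length=500_000)

    def test_hotspot_layout_membership(self):
        """Markers at +50/80/120/150/260 kb downstream of an att site are
        reachable exactly when n headfuls of 45 kb exceed their offset."""
        att, glen = 1_000_000, 4_600_000
        offsets = [50_000, 80_000, 120_000, 150_000, 260_000]
        for n in range(1, 8):
            region = lt_region(att, "rightward", n, genome_length=glen)
            got = [region.contains(att + off) for off in offsets]
            expect = [n * 45_000 > off for off in offsets]
            assert got == expect


class TestHeadfulDistanceMap:
    def test_single_bidirectional_site_450kb(self):
        dm = headful_distance_map(450_000, [(0, "both")], resolution=1_000)
        assert int(dm["headfuls"].max()) == 5
        frac = headful_fraction_within(dm, 5)
        assert frac.loc[frac["k"] == 5, "fraction_within"].iloc[0] == 1.0

    def test_bin_adjacent_to_site_is_one_headful(self):
        dm = headful_distance_map(450_000, [(0, "both")], resolution=1_000)
        assert int(dm.loc[dm["bin_start"] == 1_000, "headfuls"].iloc[0]) == 1
        assert int(dm.loc[dm["bin_start"] == 0, "headfuls"].iloc[0]) == 0

    def test_matches_per_base_exhaustive_oracle(self):
        glen, h = 30_000, 4_500
        sites = [(2_000, "rightward"), (17_500, "both"), (29_000, "leftward")]
        dm = headful_distance_map(glen, sites, headful_size=h, resolution=1)
        got = dm["headfuls"].to_numpy()
        for p in range(0, glen, 251):  # sampled per-base oracle
            best = None
            for s, d in sites:
                dists = []
                if d in ("rightward", "both"):
                    dists.append((p - s) % glen)
                if d in ("leftward", "both"):
                    dists.append((s - p) % glen)
                for dist in dists:
                    hd = -(-dist // h)
                    best = hd if best is None else min(best, hd)
            assert got[p] == best

    def test_antipodal_sites_halve_distances(self):
        glen = 360_000
        one = headful_distance_map(glen, [(0, "both")], resolution=1_000)
        two = headful_distance_map(glen, [(0, "both"), (glen // 2, "both")],
                                   resolution=1_000)
        assert int(two["headfuls"].max()) * 2 == int(one["headfuls"].max())
        assert (two["headfuls"] <= one["headfuls"]).all()

    def test_no_sites_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            headful_distance_map(10_000, [])


class TestDefenseSpotFraction:
    def frame(self, spot_ids):
        return pd.DataFrame({"spot_id": spot_ids})

    def test_all_in_prophage_spots(self):
        assert defense_in_prophage_spot_fraction(
            self.frame(["s1", "s1", "s2"]), {"s1", "s2"}
        ) == 100.0

    def test_none_in_prophage_spots(self):
        assert defense_in_prophage_spot_fraction(self.frame(["s3"]), {"s1"}) == 0.0

    def test_29_of_40_is_72_5(self):
        ids = ["p"] * 29 + ["q"] * 11
        assert defense_in_prophage_spot_fraction(self.frame(ids), {"p"}) == 72.5

    def test_zero_defenses_undefined(self):
        assert defense_in_prophage_spot_fraction(self.frame([]), {"p"}) is None
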