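"""Integrase, orientation, terminase-pair and pac classification against
exhaustive rule oracles and boundary semantics."""

import numpy as np
import pandas as pd
import pytest

from ltscope.prophagecls import (
    ProphageCall,
    TerminaseThresholds,
    classify_pac,
    detect_integrase,
    find_terminase_pair,
    orient_prophage,
    summarize_prophage_cohort,
)


def hmm_frame(rows):
    return pd.DataFrame(
        rows, columns=["protein", "profile_accession", "evalue", "profile_coverage"]
    )


def ter_frame(rows):
    return pd.DataFrame(
        rows, columns=["query", "ref_role", "evalue", "query_coverage", "pct_similarity"]
    )


class TestDetectIntegrase:
    def test_single_tyrosine_hit(self):
        hits = hmm_frame([("g1", "PF00589", 1e-5, 0.8)])
        assert detect_integrase(["g1"], hits) == ("g1", "left")

    def test_serine_pair_requires_both_profiles(self):
        hits = hmm_frame([("g1", "PF00239", 1e-6, 0.9)])
        assert detect_integrase(["g1", "g2"], hits) is None
        both = hmm_frame(
            [("g1", "PF00239", 1e-6, 0.9), ("g1", "PF07508", 1e-6, 0.9)]
        )
        assert detect_integrase(["g1", "g2"], both) == ("g1", "left")

    def test_evalue_threshold_is_strict(self):
        assert detect_integrase(["g1"], hmm_frame([("g1", "PF00589", 1e-3, 0.9)])) is None

    def test_coverage_threshold_is_inclusive(self):
        hits = hmm_frame([("g1", "PF00589", 1e-5, 0.5)])
        assert detect_integrase(["g1"], hits) == ("g1", "left")

    def test_nearest_end_qualifier_wins_with_end_label(self):
        genes = [f"g{i}" for i in range(10)]
        hits = hmm_frame(
            [("g4", "PF00589", 1e-9, 0.9), ("g8", "PF00589", 1e-5, 0.9)]
        )
        assert detect_integrase(genes, hits) == ("g8", "right")

    def test_malformed_row_reported_with_number(self):
        hits = hmm_frame([("g1", "PF00589", "not-a-number", 0.9)])
        with pytest.raises(ValueError, match="row 0"):
            detect_integrase(["g1"], hits)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_filter_oracle(self, seed):
        """Planted Int among decoy sub-threshold hits, vs a brute-force filter."""
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        rows = []
        for g in rng.choice(genes, size=15, replace=False):
            profile = rng.choice(["PF00589", "PF00239", "PF07508", "PF99999"])
            rows.append(
                (g, profile, float(10.0 ** rng.uniform(-8, 0)), float(rng.uniform(0, 1)))
            )
        planted = genes[int(rng.integers(0, 3))]
        rows.append((planted, "PF00589", 1e-9, 0.9))
        hits = hmm_frame(rows)

        # oracle: exhaustive re-application of the written rule
        ok: dict[str, set] = {}
        for g, p, ev, cov in rows:
            if ev < 1e-3 and cov >= 0.5:
                ok.setdefault(g, set()).add(p)
        quals = [
            g for g in genes
            if "PF00589" in ok.get(g, set())
            or {"PF00239", "PF07508"} <= ok.get(g, set())
        ]
        n = len(genes)
        expected = min(quals, key=lambda g: (min(genes.index(g), n - 1 - genes.index(g)),
                                             genes.index(g)))
        got = detect_integrase(genes, hits)
        assert got is not None and got[0] == expected

    def test_filter_is_idempotent(self):
        """Pre-filtering the hit table to passing rows changes nothing."""
        hits = hmm_frame(
            [("g0", "PF00589", 1e-9, 0.9), ("g3", "PF00589", 0.5, 0.9),
             ("g5", "PF00589", 1e-9, 0.2)]
        )
        genes = [f"g{i}" for i in range(6)]
        passing = hits[(hits["evalue"] < 1e-3) & (hits["profile_coverage"] >= 0.5)]
        assert detect_integrase(genes, hits) == detect_integrase(genes, passing)


class TestOrientation:
    def make(self, n, int_idx):
        genes = tuple(f"g{i}" for i in range(n))
        return ProphageCall("G", 0, n * 1000, genes, int_gene=f"g{int_idx}")

    def test_first_gene_packs_rightward(self):
        assert orient_prophage(self.make(40, 0)) == "packaging_rightward"

    def test_last_gene_packs_leftward(self):
        assert orient_prophage(self.make(40, 39)) == "packaging_leftward"

    def test_interior_integrase_is_unknown(self):
        assert orient_prophage(self.make(40, 19)) == "unknown"

    def test_terminal_zone_is_ten_percent_min_one(self):
        assert orient_prophage(self.make(40, 3)) == "packaging_rightward"
        assert orient_prophage(self.make(40, 4)) == "unknown"
        assert orient_prophage(self.make(5, 0)) == "packaging_rightward"
        assert orient_prophage(self.make(5, 1)) == "unknown"


class TestTerminasePair:
    def test_adjacent_keyword_pair(self):
        genes = ["a", "b"]
        products = {"a": "Phage Terminase Small Subunit", "b": "terminase large subunit x"}
        got = find_terminase_pair(genes, products, ter_frame([]))
        assert got == ("a", "b", None)

    def test_gap_beyond_window_rejected(self):
        genes = [f"g{i}" for i in range(12)]
        products = {"g5": "terminase small subunit", "g9": "terminase large subunit"}
        assert find_terminase_pair(genes, products, ter_frame([])) is None

    def test_gap_at_window_boundary_accepted(self):
        genes = [f"g{i}" for i in range(12)]
        products = {"g5": "terminase small subunit", "g8": "terminase large subunit"}
        got = find_terminase_pair(genes, products, ter_frame([]))
        assert got == ("g5", "g8", None)

    def test_homology_hits_supply_candidates_and_min_similarity(self):
        genes = ["a", "b"]
        hits = ter_frame(
            [("a", "TerS", 1e-9, 0.8, 35.0),
             ("b", "TerL", 1e-9, 0.8, 72.0),
             ("b", "TerL", 1e-8, 0.7, 64.0)]  # min across passing refs
        )
        got = find_terminase_pair(genes, {}, hits)
        assert got == ("a", "b", 64.0)

    def test_failing_homology_hits_ignored(self):
        genes = ["a", "b"]
        hits = ter_frame(
            [("a", "TerS", 1e-4, 0.8, 35.0),   # evalue not < 1e-5
             ("b", "TerL", 1e-9, 0.3, 72.0)]   # coverage below 0.5
        )
        assert find_terminase_pair(genes, {}, hits) is None

    def test_smallest_gap_then_highest_similarity_wins(self):
        genes = [f"g{i}" for i in range(6)]
        hits = ter_frame(
            [("g0", "TerS", 1e-9, 0.8, 30.0),
             ("g1", "TerL", 1e-9, 0.8, 55.0),
             ("g3", "TerL", 1e-9, 0.8, 90.0)]
        )
        got = find_terminase_pair(genes, {}, hits)
        assert got == ("g0", "g1", 55.0)  # gap 1 beats gap 3 despite similarity


class TestClassifyPac:
    def make(self, sim):
        return ProphageCall("G", 0, 1000, ("a", "b"), terS_gene="a",
                            terL_gene="b", terL_similarity=sim)

    def test_high_similarity_is_pac(self):
        assert classify_pac(self.make(85.0)) is True

    def test_exactly_sixty_is_not_pac(self):
        assert classify_pac(self.make(60.0)) is False

    def test_no_terminase_pair_is_not_pac(self):
        call = ProphageCall("G", 0, 1000, ("a",))
        assert classify_pac(call) is False

    def test_pac_count_monotone_in_threshold(self):
        sims = [10, 35, 55, 60, 61, 70, 85, 95]
        calls = [self.make(float(s)) for s in sims]
        counts = [
            sum(classify_pac(c, thr) for c in calls) for thr in (30, 50, 60, 70, 90)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCohortSummary:
    def test_reported_percentage_convention(self):
        calls = []
        for i in range(9716):
            c = ProphageCall("G", 0, 1000, ("a", "b"), int_gene="a")
            if i < 5961:
                c.terS_gene, c.terL_gene = "a", "b"
            calls.append(c)
        s = summarize_prophage_cohort(calls)
        assert s["with_int"] == 9716 and s["with_terminases"] == 5961
        assert s["pct_with_terminases"] == 61.4

    def test_empty_cohort_percentages_undefined(self):
        s = summarize_prophage_cohort([])
        assert s["total"] == 0 and s["pct_with_terminases"] is None

    def test_planted_cohort_recovered(self, pipeline_result, default_collection):
        _, _, truth = default_collection
        _, result = pipeline_result
        s = summarize_prophage_cohort(result.prophage_calls)
        assert s["total"] == len(truth.prophages)
        assert s["pac_related"] == int(truth.prophages["pac_related"].sum())
        by_id = {c.prophage_id: c for c in result.prophage_calls}
        for rec in truth.prophages.itertuples():
            call = by_id[rec.prophage_id]
            assert call.orientation == rec.orientation
            assert call.int_gene == rec.int_gene
            assert call.pac_related == rec.pac_related
            assert call.terS_gene == (rec.terS_gene if pd.notna(rec.terS_gene) else None)
            assert call.terL_gene == (rec.terL_gene if pd.notna(rec.terL_gene) else None)
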