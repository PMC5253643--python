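"""Cut-site derivation and breakdown-product enumeration."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from cleavescan import (
    CombinationCapError,
    ConsensusOccurrence,
    ProteinRecord,
    STANDARD_AA,
    combined_digest,
    cut_sites,
    distinct_fragments,
    enumerate_scenarios,
    fragments_for_subset,
    scan,
)


def record(seq, rid="p1"):
    return ProteinRecord(id=rid, sequence=seq)


def occ(rid, start, end, cut, word="DEED", pattern="caspase3"):
    return ConsensusOccurrence(
        protein_id=rid, pattern_name=pattern, matched_subsequence=word,
        start=start, end=end, cleavage_position=cut,
    )


class TestCutSites:
    def test_overlapping_hits_give_distinct_sites(self):
        rec = record("A" * 700, "194")
        occs = [occ("194", 616, 619, 619), occ("194", 619, 622, 622)]
        assert cut_sites(occs, rec) == [619, 622]

    def test_terminal_cut_suppressed(self):
        rec = record("ADEED")
        occs = scan(rec, __import__("cleavescan").CASPASE3)
        assert [o.cleavage_position for o in occs] == [5]
        assert cut_sites(occs, rec) == []

    def test_shared_cleavage_position_deduplicated(self):
        rec = record("A" * 100)
        occs = [occ("p1", 10, 13, 13), occ("p1", 12, 13, 13, pattern="calpain2", word="VD")]
        assert cut_sites(occs, rec) == [13]

    def test_foreign_occurrence_rejected(self):
        rec = record("A" * 100, "mine")
        with pytest.raises(ValueError, match="belongs to"):
            cut_sites([occ("other", 1, 4, 4)], rec)


class TestFragmentsForSubset:
    def test_single_cut_splits_in_two(self):
        rec = record("MKLVDEEDAG")
        frags = fragments_for_subset(rec, {4})
        assert [(f.start, f.end) for f in frags] == [(1, 4), (5, 10)]
        assert frags[0].sequence == "MKLV"
        assert frags[1].sequence == "DEEDAG"
        assert frags[0].left_cut == 0 and frags[1].right_cut == 10

    def test_empty_subset_returns_intact_protein(self):
        rec = record("MKLV")
        frags = fragments_for_subset(rec, set())
        assert [(f.start, f.end) for f in frags] == [(1, 4)]

    def test_two_cuts_middle_fragment_spans_between(self):
        rec = record("A" * 20)
        frags = fragments_for_subset(rec, {5, 12})
        assert [(f.start, f.end) for f in frags] == [(1, 5), (6, 12), (13, 20)]

    @pytest.mark.parametrize("bad", [0, 20, 25, -3])
    def test_out_of_range_cut_rejected(self, bad):
        with pytest.raises(ValueError):
            fragments_for_subset(record("A" * 20), {bad})


class TestEnumerateScenarios:
    def test_two_sites_three_scenarios(self):
        rec = record("A" * 30)
        scen = enumerate_scenarios(rec, [10, 20])
        assert set(scen) == {(10,), (20,), (10, 20)}
        assert sorted(len(v) for v in scen.values()) == [2, 2, 3]

    def test_one_site_one_scenario(self):
        scen = enumerate_scenarios(record("A" * 10), [4])
        assert list(scen) == [(4,)]
        assert len(scen[(4,)]) == 2

    def test_three_sites_seven_scenarios_nineteen_fragment_slots(self):
        # Σ(|s|+1) over the 7 non-empty subsets: 3·2 + 3·3 + 1·4 = 19
        scen = enumerate_scenarios(record("A" * 40), [5, 15, 30])
        assert len(scen) == 7
        assert sum(len(v) for v in scen.values()) == 19

    def test_cap_guard(self):
        rec = record("A" * 100)
        sites = list(range(2, 40, 2))
        with pytest.raises(CombinationCapError):
            enumerate_scenarios(rec, sites, max_sites=16)
        # raising the cap un-trips the guard
        assert len(enumerate_scenarios(rec, sites[:5], max_sites=5)) == 31


class TestDistinctFragments:
    def test_two_sites_give_the_five_named_fragments(self):
        rec = record("A" * 30)
        frags = distinct_fragments(rec, [10, 20])
        assert [(f.start, f.end) for f in frags] == [
            (1, 10), (1, 20), (11, 20), (11, 30), (21, 30),
        ]

    def test_no_sites_no_fragments(self):
        assert distinct_fragments(record("A" * 10), []) == []

    @pytest.mark.parametrize("k", range(0, 11))
    def test_closed_form_and_union_oracle(self, k):
        """(k+1)(k+2)/2 − 1 distinct fragments, equal to the brute-force
        union over all 2^k − 1 cleavage scenarios."""
        length = 3 * (k + 1) + 2
        rng = random.Random(k)
        seq = "".join(rng.choices(STANDARD_AA, k=length))
        rec = record(seq)
        sites = sorted(rng.sample(range(1, length), k))
        frags = distinct_fragments(rec, sites)
        assert len(frags) == (k + 1) * (k + 2) // 2 - 1
        union = set()
        for r in range(1, k + 1):
            for subset in itertools.combinations(sites, r):
                union.update(
                    (f.start, f.end) for f in fragments_for_subset(rec, subset)
                )
        assert {(f.start, f.end) for f in frags} == union
        assert len({(f.start, f.end) for f in frags}) == len(frags)


@given(
    length=st.integers(10, 120),
    data=st.data(),
)
@settings(derandomize=True, max_examples=60)
def test_partition_property(length, data):
    """Every scenario's fragments tile the substrate exactly."""
    rng = random.Random(length)
    seq = "".join(rng.choices(STANDARD_AA, k=length))
    rec = record(seq)
    k = data.draw(st.integers(0, min(5, length - 1)))
    sites = sorted(data.draw(
        st.sets(st.integers(1, length - 1), min_size=k, max_size=k)
    ))
    for subset_frags in enumerate_scenarios(rec, sites).values():
        assert sum(f.length for f in subset_frags) == length
        assert "".join(f.sequence for f in subset_frags) == seq
        assert all(f.length >= 1 for f in subset_frags)


class TestCombinedDigest:
    def test_single_pattern_equals_single_protease_digest(self, table4, caspase3):
        single = combined_digest(table4, [caspase3])
        occs = scan(table4, caspase3)
        assert single.cut_sites == cut_sites(occs, table4)
        assert single.occurrences == {"caspase3": occs}
        assert all(v == ("caspase3",) for v in single.site_proteases.values())

    def test_cut_sites_are_union_of_single_digests(self, table4, caspase3, calpain2):
        both = combined_digest(table4, [caspase3, calpain2])
        a = combined_digest(table4, [caspase3])
        b = combined_digest(table4, [calpain2])
        assert both.cut_sites == sorted(set(a.cut_sites) | set(b.cut_sites))
        shared = set(a.cut_sites) & set(b.cut_sites)
        for site in shared:
            assert both.site_proteases[site] == ("calpain2", "caspase3")

    def test_planted_two_site_fixture_gives_five_distinct_fragments(self):
        from cleavescan import plant_motifs

        truth = plant_motifs(
            80, [("caspase3", 20), ("calpain2", 50)], seed=5, collision_free=True
        )
        result = combined_digest(truth.record, list(__import__("cleavescan").builtin_patterns().values()))
        assert len(result.cut_sites) == 2
        assert len(result.distinct_fragments) == 5

    def test_per_site_mode_one_scenario_per_site(self, table4, caspase3):
        result = combined_digest(table4, [caspase3], mode="per-site")
        assert set(result.scenarios) == {(s,) for s in result.cut_sites}
        assert all(len(v) == 2 for v in result.scenarios.values())

    def test_determinism(self, table4, caspase3, calpain2):
        a = combined_digest(table4, [caspase3, calpain2])
        b = combined_digest(table4, [caspase3, calpain2])
        assert a.cut_sites == b.cut_sites
        assert [(f.start, f.end) for f in a.distinct_fragments] == [
            (f.start, f.end) for f in b.distinct_fragments
        ]

    def test_requires_a_pattern_and_valid_mode(self, table4, caspase3):
        with pytest.raises(ValueError):
            combined_digest(table4, [])
        with pytest.raises(ValueError):
            combined_digest(table4, [caspase3], mode="everything")
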