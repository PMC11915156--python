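import itertools

import pytest

from cysredox.redox_classify import CysteineSiteObservation, classify_sites
from cysredox.repro_regions import (
    ALL_PATTERNS,
    REACTIVE_LETTERS,
    REGION_LETTERS,
    RedoxPattern,
    assign_region,
    assign_regions,
    assignments_from_region_table,
    load_reactive_site_table,
    reproducible_sites,
    select_reactive,
    venn_counts,
)


def obs(acc, pos, label, cond, rep):
    return CysteineSiteObservation(acc, pos, label, cond, rep)


class TestReproducibilityRule:
    def test_two_of_three_passes(self):
        sites = reproducible_sites([obs("P", 5, "reduced", "RT", r) for r in (1, 2)])
        assert len(sites) == 1 and sites[0].n_replicates_detected == 2

    def test_single_replicate_fails(self):
        assert reproducible_sites([obs("P", 5, "reduced", "RT", 1)]) == []

    def test_same_site_reproducible_in_both_categories(self):
        observations = [obs("P", 5, "reduced", "RT", r) for r in (1, 2)]
        observations += [obs("P", 5, "oxidized", "RT", r) for r in (2, 3)]
        labels = {s.label for s in reproducible_sites(observations)}
        assert labels == {"reduced", "oxidized"}

    def test_rule_matches_brute_force_over_all_replicate_subsets(self):
        # enumerate every subset of replicates per label and compare against
        # a direct |subset| >= 2 check
        for red_reps in itertools.chain.from_iterable(
            itertools.combinations((1, 2, 3), k) for k in range(4)
        ):
            observations = [obs("P", 1, "reduced", "RT", r) for r in red_reps]
            expected = 1 if len(red_reps) >= 2 else 0
            assert len(reproducible_sites(observations)) == expected

    def test_unlabeled_never_reproducible(self):
        observations = [obs("P", 5, "unlabeled", "RT", r) for r in (1, 2, 3)]
        assert reproducible_sites(observations) == []

    def test_threshold_above_replicate_count_is_config_error(self):
        with pytest.raises(ValueError):
            reproducible_sites([], min_replicates=4, n_replicates=3)


def _brute_force_classes(rt, cold):
    """Independent set-logic oracle for the class semantics."""
    classes = set()
    if rt and cold and rt != cold:
        classes.add("dynamic")
    shifted_to_ox = rt and cold and cold.issubset({"oxidized", "reduced"}) and (
        ("oxidized" in cold and "oxidized" not in rt)
        or (cold == {"oxidized"} and rt == {"oxidized", "reduced"})
    )
    if shifted_to_ox:
        classes.add("reactive")
    if not cold:
        classes.add("rt_exclusive")
    if not rt:
        classes.add("cold_exclusive")
    if rt and rt == cold:
        classes.add("stable")
    return classes


class TestRegionAlgebra:
    def test_fifteen_realizable_patterns(self):
        subsets = [frozenset(s) for s in ({}, {"oxidized"}, {"reduced"}, {"oxidized", "reduced"})]
        realizable = [(a, b) for a in subsets for b in subsets if a or b]
        assert len(realizable) == 15
        letters = {assign_region(RedoxPattern(a, b))[0] for a, b in realizable}
        assert letters == set(REGION_LETTERS)

    def test_class_counts_by_enumeration(self):
        counts = {"dynamic": 0, "reactive": 0, "rt_exclusive": 0, "cold_exclusive": 0, "stable": 0}
        for pattern in ALL_PATTERNS:
            _, classes = assign_region(pattern)
            for c in classes:
                counts[c] += 1
        assert counts == {
            "dynamic": 6,
            "reactive": 3,
            "rt_exclusive": 3,
            "cold_exclusive": 3,
            "stable": 3,
        }

    def test_classes_match_brute_force_oracle(self):
        for pattern in ALL_PATTERNS:
            _, classes = assign_region(pattern)
            assert set(classes) == _brute_force_classes(
                set(pattern.rt_labels), set(pattern.cold_labels)
            )

    @pytest.mark.parametrize(
        "rt,cold,letter,must_have,must_not",
        [
            ({"reduced"}, {"oxidized"}, "L", {"dynamic", "reactive"}, {"stable"}),
            ({"oxidized", "reduced"}, {"oxidized"}, "M", {"dynamic", "reactive"}, set()),
            ({"reduced"}, {"oxidized", "reduced"}, "N", {"dynamic", "reactive"}, set()),
            ({"reduced"}, {"reduced"}, "F", {"stable"}, {"dynamic"}),
            ({"oxidized"}, set(), "A", {"rt_exclusive"}, {"dynamic"}),
            ({"oxidized"}, {"reduced"}, "E", {"dynamic"}, {"reactive"}),
        ],
    )
    def test_named_patterns(self, rt, cold, letter, must_have, must_not):
        got_letter, classes = assign_region(RedoxPattern(frozenset(rt), frozenset(cold)))
        assert got_letter == letter
        assert must_have <= classes
        assert not (must_not & classes)

    def test_both_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            RedoxPattern(frozenset(), frozenset())


class TestVennCounts:
    def _one_site_per_pattern(self):
        sites = []
        for i, pattern in enumerate(ALL_PATTERNS):
            for label in pattern.rt_labels:
                sites += [obs(f"P{i}", 10, label, "RT", r) for r in (1, 2)]
            for label in pattern.cold_labels:
                sites += [obs(f"P{i}", 10, label, "Cold", r) for r in (1, 2)]
        return sites

    def test_counts_partition_sites(self):
        assignments = assign_regions(reproducible_sites(self._one_site_per_pattern()))
        counts = venn_counts(assignments)
        assert counts["n_sites"] == 15
        assert sum(counts["sites_by_region"].values()) == 15
        assert all(v == 1 for v in counts["sites_by_region"].values())
        assert counts["sites_by_class"]["dynamic"] == 6
        assert counts["sites_by_class"]["reactive"] == 3

    def test_empty_input_gives_zero_counts(self):
        counts = venn_counts([])
        assert counts["n_sites"] == 0
        assert set(counts["sites_by_region"].values()) == {0}

    def test_protein_counts_deduplicate_within_region(self):
        # two reproducible reduced-stable sites on one protein count once
        observations = []
        for pos in (10, 50):
            for cond in ("RT", "Cold"):
                observations += [obs("P1", pos, "reduced", cond, r) for r in (1, 2)]
        counts = venn_counts(assign_regions(reproducible_sites(observations)))
        assert counts["sites_by_region"]["F"] == 2
        assert counts["proteins_by_region"]["F"] == 1

    def test_invariant_under_replicate_relabeling(self):
        observations = self._one_site_per_pattern()
        relabeled = [
            obs(o.accession, o.position, o.label, o.condition, {1: 3, 2: 1, 3: 2}[o.replicate])
            for o in observations
        ]
        a = venn_counts(assign_regions(reproducible_sites(observations)))
        b = venn_counts(assign_regions(reproducible_sites(relabeled)))
        assert a == b


class TestRecoveryOnSyntheticTruth:
    def test_perfect_detection_recovers_planted_regions_exactly(self, perfect_bundle):
        psms = [p for recs in perfect_bundle.psm_tables.values() for p in recs]
        observations = classify_sites(psms, perfect_bundle.proteome)
        assignments = assign_regions(reproducible_sites(observations))
        truth = {
            (s.accession, s.position): s.region
            for s in perfect_bundle.sites
            if s.region is not None
        }
        got = {(a.accession, a.position): a.region for a in assignments}
        assert got == truth


class TestPublishedReactiveSites:
    def test_reactive_selector_on_published_table(self):
        df = load_reactive_site_table()
        assignments = assignments_from_region_table(df)
        reactive = select_reactive(assignments)
        assert len({(a.accession, a.position) for a in reactive}) == 34
        assert all(a.region in REACTIVE_LETTERS for a in reactive)

    def test_region_l_proteins(self):
        df = load_reactive_site_table()
        region_l = df[df["region"] == "L"]
        assert set(zip(region_l["accession"], region_l["position"])) == {
            ("Q9DCS9", 77),   # Ndufb10
            ("Q9CRB9", 183),  # Chchd3 / Mic19
            ("P10126", 411),  # Eef1a1
            ("A0A1S6GWI0", 70),  # Ndufa8
            ("P17563", 8),    # Selenbp1
        }
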