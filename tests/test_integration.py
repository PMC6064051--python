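"""Multi-omics integration bookkeeping: profiles, sectors, co-occurrence,
cumulative tiers."""

import numpy as np
import pytest

from druggability.cohort_io import SampleTraits
from druggability.integration import (
    build_profiles,
    cooccurrence_report,
    cumulative_tier_summary,
    drug_class_sectors,
    multiomics_fraction,
)
from druggability.knowledgebase import Effect
from druggability.variant_annotation import NON_SPECIFIC, SPECIFIC, DruggabilityCall

VIZ = tuple(f"class{i}" for i in range(10))


def call(
    sample="T1",
    gene="BRAF",
    level="mutation",
    effect=Effect.SENSITIVE,
    evidence="fda_approved",
    specificity=NON_SPECIFIC,
    drug="dabrafenib",
    classes=("class0",),
    variant_key=None,
):
    c = DruggabilityCall(
        sample_id=sample,
        cancer_type="SKCM",
        gene=gene,
        variant_key=variant_key or f"{gene}:X@{level}",
        data_level=level,
        effect=effect,
        specificity=specificity,
        chosen_drug=drug,
        chosen_evidence=evidence,
    )
    object.__setattr__(c, "drug_classes", frozenset(classes))
    return c


def traits_for(samples):
    return [SampleTraits(sample_id=s, cancer_type="SKCM") for s in samples]


def complete(samples):
    return {s: frozenset({"mutation", "mrna", "protein"}) for s in samples}


class TestProfiles:
    def test_levels_supporting_druggability_collected(self):
        calls_mut = [call("T1", "BRAF", "mutation")]
        calls_expr = [call("T1", "AKT3", "mrna")]
        (p,) = build_profiles(calls_mut, calls_expr, [], traits_for(["T1"]), complete(["T1"]))
        assert p.druggable_levels == frozenset({"mutation", "mrna"})

    def test_no_sensitive_calls_empty_levels(self):
        calls = [call("T1", effect=Effect.RESISTANT)]
        (p,) = build_profiles(calls, [], [], traits_for(["T1"]), complete(["T1"]))
        assert p.druggable_levels == frozenset()

    def test_incomplete_profiles_excluded_from_denominator(self):
        profiled = {
            "T1": frozenset({"mutation", "mrna", "protein"}),
            "T2": frozenset({"mutation", "mrna"}),  # no protein data
        }
        profiles = build_profiles([], [], [], traits_for(["T1", "T2"]), profiled)
        assert [p.sample_id for p in profiles] == ["T1"]

    def test_phosphoprotein_counts_as_protein_level(self):
        calls = [call("T1", "EGFR", "phosphoprotein")]
        (p,) = build_profiles([], calls, [], traits_for(["T1"]), complete(["T1"]))
        assert p.druggable_levels == frozenset({"protein"})


class TestMultiomicsFraction:
    def test_planted_four_of_ten(self):
        samples = [f"T{i}" for i in range(10)]
        mut = [call(s, level="mutation") for s in samples[:4]]
        expr = [call(s, "AKT3", "mrna") for s in samples[:4]]
        profiles = build_profiles(mut, expr, [], traits_for(samples), complete(samples))
        frac, num, den = multiomics_fraction(profiles)
        assert (frac, num, den) == (0.4, 4, 10)

    def test_mutation_only_cohort_is_zero(self):
        samples = [f"T{i}" for i in range(5)]
        mut = [call(s) for s in samples]
        profiles = build_profiles(mut, [], [], traits_for(samples), complete(samples))
        assert multiomics_fraction(profiles)[0] == 0.0

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ValueError):
            multiomics_fraction([])

    def test_independent_levels_match_inclusion_exclusion(self):
        rng = np.random.default_rng(0)
        n = 2000
        p_m, p_r, p_p = 0.3, 0.2, 0.25
        samples = [f"T{i}" for i in range(n)]
        mut, mrna, prot = [], [], []
        for s in samples:
            if rng.random() < p_m:
                mut.append(call(s, level="mutation"))
            if rng.random() < p_r:
                mrna.append(call(s, "AKT3", "mrna"))
            if rng.random() < p_p:
                prot.append(call(s, "EGFR", "protein"))
        profiles = build_profiles(mut, mrna + prot, [], traits_for(samples), complete(samples))
        frac, _, _ = multiomics_fraction(profiles)
        # P(>=2 of 3 independent) by inclusion-exclusion
        expected = (
            p_m * p_r + p_m * p_p + p_r * p_p - 2 * p_m * p_r * p_p
        )
        tol = 3 * np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < tol

    def test_invariant_to_call_table_merge_order(self):
        samples = [f"T{i}" for i in range(50)]
        rng = np.random.default_rng(1)
        mut = [call(s) for s in samples if rng.random() < 0.5]
        expr = [call(s, "AKT3", "mrna") for s in samples if rng.random() < 0.5]
        a = build_profiles(mut, expr, [], traits_for(samples), complete(samples))
        b = build_profiles(mut[::-1], expr[::-1], [], traits_for(samples), complete(samples))
        assert multiomics_fraction(a) == multiomics_fraction(b)


class TestSectors:
    def test_within_class_multi_gene_link(self):
        calls = [
            call("T1", "ESR1", "mrna", classes=("class1",)),
            call("T1", "PGR", "mrna", classes=("class1",)),
        ]
        profiles = build_profiles([], calls, [], traits_for(["T1"]), complete(["T1"]))
        _, cross, within = drug_class_sectors(profiles, VIZ)
        assert cross.empty
        assert within.genes.tolist() == ["ESR1;PGR"]

    def test_cross_class_link(self):
        calls = [
            call("T1", "EGFR", "mutation", classes=("class2",)),
            call("T1", "CDK6", "mrna", classes=("class3",)),
        ]
        profiles = build_profiles(calls[:1], calls[1:], [], traits_for(["T1"]), complete(["T1"]))
        _, cross, _ = drug_class_sectors(profiles, VIZ)
        assert len(cross) == 1
        assert (cross.class_a.iloc[0], cross.class_b.iloc[0]) == ("class2", "class3")

    def test_single_biomarker_no_links(self):
        profiles = build_profiles([call("T1")], [], [], traits_for(["T1"]), complete(["T1"]))
        _, cross, within = drug_class_sectors(profiles, VIZ)
        assert cross.empty and within.empty

    def test_class_outside_viz_subset_excluded_from_sectors(self):
        calls = [call("T1", classes=("unlisted class",))]
        profiles = build_profiles(calls, [], [], traits_for(["T1"]), complete(["T1"]))
        sectors, _, _ = drug_class_sectors(profiles, VIZ)
        assert sectors.empty

    def test_wrong_viz_count_rejected(self):
        with pytest.raises(ValueError, match="exactly 10"):
            drug_class_sectors([], ("a", "b"))


class TestCooccurrence:
    def test_sensitive_resistant_pair_flagged(self):
        calls = [
            call("T1", "BRAF", variant_key="BRAF:V600E"),
            call("T1", "RAC1", effect=Effect.RESISTANT, variant_key="RAC1:P29S"),
        ]
        table = cooccurrence_report(calls)
        assert len(table) == 1
        assert bool(table.sensitive_resistant_pair.iloc[0])

    def test_distinct_class_sensitive_pair_is_combination_candidate(self):
        calls = [
            call("T1", "PIK3CA", classes=("class4",), variant_key="PIK3CA:E545K"),
            call("T1", "ESR1", "mrna", classes=("class5",), variant_key="ESR1:high"),
        ]
        table = cooccurrence_report(calls)
        assert bool(table.combination_candidate.iloc[0])

    def test_single_alteration_no_pairs(self):
        assert cooccurrence_report([call("T1")]).empty


class TestCumulativeTiers:
    def test_planted_tier_fractions_accumulate(self):
        n = 100
        samples = [f"T{i}" for i in range(n)]
        tiers = ["fda_approved", "clinical_trial", "case_report", "preclinical", "hotspot3d"]
        planted = [5, 10, 15, 20, 25]
        calls = []
        start = 0
        for tier, count in zip(tiers, planted):
            level = "cluster_putative" if tier == "hotspot3d" else "mutation"
            for s in samples[start : start + count]:
                calls.append(call(s, level=level, evidence=tier))
            start += count
        table = cumulative_tier_summary(calls, samples)
        nonspec = table[table.setting == "non_specific"].set_index("tier").cumulative_fraction
        assert nonspec.tolist() == [0.05, 0.15, 0.30, 0.50, 0.75]

    def test_no_calls_all_zero(self):
        table = cumulative_tier_summary([], ["T1", "T2"])
        assert (table.cumulative_fraction == 0).all()

    def test_single_tier_step_function(self):
        samples = ["T1", "T2", "T3", "T4"]
        calls = [call("T1", evidence="case_report"), call("T2", evidence="case_report")]
        table = cumulative_tier_summary(calls, samples)
        nonspec = table[table.setting == "non_specific"].set_index("tier").cumulative_fraction
        assert nonspec["fda_approved"] == 0
        assert nonspec["clinical_trial"] == 0
        assert nonspec["case_report"] == nonspec["preclinical"] == nonspec["hotspot3d"] == 0.5

    def test_monotone_and_nonspecific_dominates(self):
        rng = np.random.default_rng(2)
        samples = [f"T{i}" for i in range(200)]
        tiers = ["fda_approved", "clinical_trial", "case_report", "preclinical"]
        calls = []
        for s in samples:
            if rng.random() < 0.5:
                calls.append(
                    call(
                        s,
                        evidence=tiers[rng.integers(4)],
                        specificity=SPECIFIC if rng.random() < 0.4 else NON_SPECIFIC,
                    )
                )
        table = cumulative_tier_summary(calls, samples)
        for setting in ("specific", "non_specific"):
            curve = table[table.setting == setting].cumulative_fraction.tolist()
            assert curve == sorted(curve)
            assert all(0 <= v <= 1 for v in curve)
        spec = table[table.setting == "specific"].cumulative_fraction.to_numpy()
        nonspec = table[table.setting == "non_specific"].cumulative_fraction.to_numpy()
        assert (nonspec >= spec).all()
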