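"""Knowledgebase matching and call resolution, checked against an
exhaustive brute-force oracle."""

import numpy as np
import pytest
from conftest import make_entry
from oracles import OracleEntry, OracleRecord, brute_force_match, brute_force_resolve

from druggability.cohort_io import MutationRecord
from druggability.knowledgebase import Effect, EvidenceLevel, VariantClass
from druggability.variant_annotation import (
    NON_SPECIFIC,
    SPECIFIC,
    KnowledgebaseIndex,
    match_mutation,
    resolve_call,
    summarize_mutation_druggability,
)


def make_record(
    sample_id="T1",
    cancer_type="SKCM",
    gene="BRAF",
    protein_change="V600E",
    mutation_class="missense",
):
    return MutationRecord(
        sample_id=sample_id,
        cancer_type=cancer_type,
        gene=gene,
        protein_change=protein_change,
        mutation_class=mutation_class,
    )


class TestMatching:
    def test_position_entry_matches_any_substitution_of_reference(self):
        kb = [make_entry(variant_class=VariantClass.MISSENSE_POSITION, variant_spec="V600")]
        index = KnowledgebaseIndex(kb)
        assert match_mutation(make_record(protein_change="V600K"), index) == kb
        # reference amino acid must agree
        assert match_mutation(make_record(protein_change="A600K"), index) == []

    def test_range_entry_matches_start_codon_inside(self):
        kb = [
            make_entry(
                gene="EGFR",
                variant_class=VariantClass.INFRAME_INDEL_RANGE,
                variant_spec="729-761:inframe_del",
            )
        ]
        index = KnowledgebaseIndex(kb)
        rec = make_record(
            gene="EGFR", protein_change="E746_A750del", mutation_class="inframe_del"
        )
        assert match_mutation(rec, index) == kb
        outside = make_record(
            gene="EGFR", protein_change="E700_A704del", mutation_class="inframe_del"
        )
        assert match_mutation(outside, index) == []
        wrong_class = make_record(gene="EGFR", protein_change="E746K")
        assert match_mutation(wrong_class, index) == []

    def test_gene_mismatch_never_hits(self):
        index = KnowledgebaseIndex([make_entry()])
        assert match_mutation(make_record(gene="KRAS"), index) == []

    def test_nonsense_wildcard_position(self):
        kb = [make_entry(gene="TP53", variant_class=VariantClass.NONSENSE, variant_spec="*")]
        index = KnowledgebaseIndex(kb)
        rec = make_record(gene="TP53", protein_change="R306*", mutation_class="nonsense")
        assert match_mutation(rec, index) == kb


class TestResolve:
    def _kb(self):
        return [
            make_entry(tumor_type="SKCM", evidence_level=EvidenceLevel.FDA_APPROVED, entry_id=0),
            make_entry(
                tumor_type="THCA",
                evidence_level=EvidenceLevel.CLINICAL_TRIAL,
                drug="trametinib",
                entry_id=1,
            ),
        ]

    def test_sample_in_top_evidence_tumor_type_is_specific(self):
        kb = self._kb()
        call = resolve_call(make_record(cancer_type="SKCM"), kb, "SKCM")
        assert call.specificity == SPECIFIC
        assert call.chosen_evidence == "fda_approved"

    def test_off_label_tumor_type_borrows_top_evidence(self):
        kb = self._kb()
        call = resolve_call(make_record(cancer_type="THCA"), kb, "THCA")
        assert call.specificity == NON_SPECIFIC
        assert call.chosen_evidence == "fda_approved"

    def test_sensitive_interaction_wins_over_resistant(self):
        kb = [
            make_entry(effect=Effect.RESISTANT, evidence_level=EvidenceLevel.FDA_APPROVED, entry_id=0),
            make_entry(effect=Effect.SENSITIVE, evidence_level=EvidenceLevel.PRECLINICAL, entry_id=1),
        ]
        call = resolve_call(make_record(), kb, "SKCM")
        assert call.effect is Effect.SENSITIVE
        assert call.chosen_evidence == "preclinical"

    def test_equal_evidence_drug_tie_keeps_all_chooses_alphabetical(self):
        kb = [
            make_entry(drug="vemurafenib", entry_id=0),
            make_entry(drug="dabrafenib", entry_id=1),
        ]
        call = resolve_call(make_record(), kb, "SKCM")
        assert call.chosen_drug == "dabrafenib"
        assert call.top_drugs == ("dabrafenib", "vemurafenib")

    def test_no_matches_gives_none(self):
        assert resolve_call(make_record(), [], "SKCM") is None


class TestSummary:
    def test_toy_fraction_counting(self):
        cohort = {f"T{i}": "SKCM" for i in range(10)}
        kb = [make_entry()]
        index = KnowledgebaseIndex(kb)
        calls = [
            resolve_call(make_record(sample_id=f"T{i}"), kb, "SKCM") for i in range(2)
        ]
        table = summarize_mutation_druggability(calls, cohort)
        fda = table[(table.setting == "specific") & (table.tier == "fda_approved")]
        assert fda.cumulative_fraction.iloc[0] == pytest.approx(0.20)

    def test_best_tier_rule_and_cumulative_nesting(self):
        cohort = {"T1": "SKCM", "T2": "SKCM"}
        kb = [
            make_entry(evidence_level=EvidenceLevel.FDA_APPROVED, entry_id=0),
            make_entry(
                variant_spec="K601E",
                evidence_level=EvidenceLevel.PRECLINICAL,
                entry_id=1,
            ),
        ]
        calls = [
            resolve_call(make_record(sample_id="T1", protein_change="V600E"), [kb[0]], "SKCM"),
            resolve_call(make_record(sample_id="T1", protein_change="K601E"), [kb[1]], "SKCM"),
        ]
        table = summarize_mutation_druggability(calls, cohort)
        spec = table[table.setting == "specific"].set_index("tier").cumulative_fraction
        # sample counts once, at its best (FDA) tier; tiers nest downwards
        assert spec["fda_approved"] == 0.5
        assert spec["preclinical"] == 0.5
        assert (spec.sort_index(key=lambda s: s.map(
            {"fda_approved": 0, "clinical_trial": 1, "case_report": 2, "preclinical": 3}
        )).diff().dropna() >= 0).all()

    def test_nonspecific_dominates_specific_everywhere(self):
        table = _random_summary(seed=3)
        merged = table.pivot_table(
            index=["cancer_type", "tier"], columns="setting", values="cumulative_fraction"
        )
        assert (merged["non_specific"] >= merged["specific"] - 1e-12).all()


AMINO = "ACDEFGHIKLMNPQRSTVWY"
GENES = ["BRAF", "EGFR", "KRAS", "TP53", "PIK3CA"]
TYPES = ["SKCM", "LUAD", "COADREAD"]


def random_kb(rng, n_entries):
    entries, oracle_entries = [], []
    for i in range(n_entries):
        gene = GENES[rng.integers(len(GENES))]
        kind = rng.integers(6)
        pos = int(rng.integers(1, 80))
        ref, alt = (AMINO[k] for k in rng.choice(len(AMINO), size=2, replace=False))
        if kind == 0:
            vc, spec = VariantClass.MISSENSE_EXACT, f"{ref}{pos}{alt}"
        elif kind == 1:
            vc, spec = VariantClass.MISSENSE_POSITION, f"{ref}{pos}"
        elif kind == 2:
            end = pos + int(rng.integers(0, 20))
            vc, spec = VariantClass.AA_RANGE, f"{pos}-{end}"
        elif kind == 3:
            end = pos + int(rng.integers(0, 20))
            sub = "inframe_del" if rng.integers(2) else "inframe_ins"
            vc, spec = VariantClass.INFRAME_INDEL_RANGE, f"{pos}-{end}:{sub}"
        elif kind == 4:
            vc, spec = VariantClass.NONSENSE, "*" if rng.integers(2) else str(pos)
        else:
            vc, spec = VariantClass.FRAMESHIFT, "*" if rng.integers(2) else str(pos)
        effect = Effect.SENSITIVE if rng.random() < 0.8 else Effect.RESISTANT
        level = list(EvidenceLevel)[rng.integers(4)]
        tumor = TYPES[rng.integers(len(TYPES))]
        drug = f"drug{rng.integers(5)}"
        entries.append(
            make_entry(
                gene=gene, variant_class=vc, variant_spec=spec, tumor_type=tumor,
                effect=effect, evidence_level=level, drug=drug, entry_id=i,
            )
        )
        oracle_entries.append(
            OracleEntry(i, gene, vc.value, spec, tumor, effect.value, level.value, drug)
        )
    return entries, oracle_entries


def random_records(rng, n_records):
    records, oracle_records = [], []
    for i in range(n_records):
        gene = GENES[rng.integers(len(GENES))]
        ctype = TYPES[rng.integers(len(TYPES))]
        pos = int(rng.integers(1, 80))
        ref, alt = (AMINO[k] for k in rng.choice(len(AMINO), size=2, replace=False))
        kind = rng.integers(5)
        if kind == 0:
            mclass, change = "missense", f"{ref}{pos}{alt}"
        elif kind == 1:
            mclass, change = "nonsense", f"{ref}{pos}*"
        elif kind == 2:
            mclass, change = "frameshift", f"{ref}{pos}fs"
        elif kind == 3:
            end = pos + int(rng.integers(1, 5))
            mclass, change = "inframe_del", f"{ref}{pos}_{alt}{end}del"
        else:
            mclass, change = "inframe_ins", f"{ref}{pos}_{alt}{pos+1}ins{AMINO[rng.integers(20)]}"
        records.append(
            make_record(
                sample_id=f"T{i}", cancer_type=ctype, gene=gene,
                protein_change=change, mutation_class=mclass,
            )
        )
        oracle_records.append(OracleRecord(f"T{i}", ctype, gene, change, mclass))
    return records, oracle_records


def check_cohort_against_oracle(seed, n_entries=30, n_records=200):
    rng = np.random.default_rng(seed)
    kb, oracle_kb = random_kb(rng, n_entries)
    records, oracle_records = random_records(rng, n_records)
    index = KnowledgebaseIndex(kb)
    for rec, orec in zip(records, oracle_records):
        matches = match_mutation(rec, index)
        expected_ids = brute_force_match(orec, oracle_kb)
        assert sorted(e.entry_id for e in matches) == expected_ids
        call = resolve_call(rec, matches, rec.cancer_type)
        expected = brute_force_resolve(orec, oracle_kb, expected_ids)
        if expected is None:
            assert call is None
        else:
            assert call.effect.value == expected["effect"]
            assert call.evidence == expected["evidence"]
            assert call.chosen_drug == expected["chosen_drug"]
            assert call.specificity == expected["specificity"]
            assert tuple(sorted(call.all_matches)) == expected["all_matches"]


@pytest.mark.parametrize("seed", range(10))
def test_matching_agrees_with_brute_force_oracle(seed):
    check_cohort_against_oracle(seed)


def test_kb_row_permutation_changes_nothing_material():
    rng = np.random.default_rng(42)
    kb, _ = random_kb(rng, 20)
    records, _ = random_records(rng, 50)
    shuffled = list(kb)[::-1]
    for rec in records:
        a = resolve_call(rec, match_mutation(rec, KnowledgebaseIndex(kb)), rec.cancer_type)
        b = resolve_call(rec, match_mutation(rec, KnowledgebaseIndex(shuffled)), rec.cancer_type)
        assert (a is None) == (b is None)
        if a is not None:
            assert (a.effect, a.chosen_evidence, a.chosen_drug, a.specificity) == (
                b.effect, b.chosen_evidence, b.chosen_drug, b.specificity
            )


def _random_summary(seed):
    rng = np.random.default_rng(seed)
    kb, _ = random_kb(rng, 25)
    records, _ = random_records(rng, 150)
    index = KnowledgebaseIndex(kb)
    calls = [
        c
        for r in records
        if (c := resolve_call(r, match_mutation(r, index), r.cancer_type)) is not None
    ]
    cohort = {r.sample_id: r.cancer_type for r in records}
    return summarize_mutation_druggability(calls, cohort)
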