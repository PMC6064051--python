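import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from druggability.knowledgebase import (
    DrugClassMap,
    Effect,
    EvidenceLevel,
    KnowledgebaseEntry,
    VariantClass,
    parse_variant_spec,
)


def make_entry(
    gene="BRAF",
    variant_class=VariantClass.MISSENSE_EXACT,
    variant_spec="V600E",
    tumor_type="SKCM",
    effect=Effect.SENSITIVE,
    evidence_level=EvidenceLevel.FDA_APPROVED,
    drug="dabrafenib",
    entry_id=0,
) -> KnowledgebaseEntry:
    return KnowledgebaseEntry(
        gene=gene,
        variant_class=variant_class,
        variant_spec=variant_spec,
        tumor_type=tumor_type,
        effect=effect,
        evidence_level=evidence_level,
        drug=drug,
        drug_classes=frozenset({"test class"}),
        pubmed_id="PMID1",
        entry_id=entry_id,
        parsed=parse_variant_spec(variant_class, variant_spec),
    )


@pytest.fixture
def class_map() -> DrugClassMap:
    return DrugClassMap(
        {
            "dabrafenib": frozenset({"B-Raf inhibitor"}),
            "trametinib": frozenset({"MEK inhibitor"}),
            "erlotinib": frozenset({"EGFR inhibitor"}),
            "tamoxifen": frozenset({"Hormone therapy"}),
            "lapatinib": frozenset({"HER2 inhibitor"}),
        }
    )
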