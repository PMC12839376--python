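import textwrap

import pytest

from ddinet.knowledge import KnowledgeBase


@pytest.fixture
def toy_kb() -> KnowledgeBase:
    """Three-record knowledge base used by the hand-computed toy cohort."""
    return KnowledgeBase.from_records([
        ("acetylsalicylic acid", "warfarin", "major"),
        ("acetylsalicylic acid", "bisoprolol", "minor"),
        ("furosemide", "spironolactone", "moderate"),
    ])


@pytest.fixture
def toy_cohort_csv(tmp_path):
    """Three accepted patients; all downstream numbers are hand-computed:

    P1 (3 meds, 3 pairs): asa-warfarin major + asa-bisoprolol minor ->
       total 2, 1 major, risk moderate
    P2 (2 meds, 1 pair): furosemide-spironolactone moderate -> total 1,
       risk low
    P3 (2 meds): no listed pairs -> total 0, risk low
    """
    path = tmp_path / "cohort.csv"
    path.write_text(textwrap.dedent("""\
        patient_id,age,sex,residence,diagnosis,medications
        P1,72,male,urban,heart failure,acetylsalicylic acid; warfarin; bisoprolol
        P2,65,female,rural,heart failure,furosemide; spironolactone
        P3,49,female,rural,hypertension,paracetamol; amoxicillin
        """))
    return path


@pytest.fixture
def toy_kb_tsv(tmp_path, toy_kb):
    from ddinet.knowledge import write_knowledge_base

    path = tmp_path / "kb.tsv"
    write_knowledge_base(toy_kb, path)
    return path
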