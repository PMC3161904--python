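import pytest

from phenominer.config import default_blacklist, default_lexicons, default_specifiers
from phenominer.icd10 import build_dictionary
from phenominer.synthetic import CohortConfig, make_cohort, make_dictionary


@pytest.fixture(scope="session")
def tiny_dictionary():
    """Hand-written dictionary: multiword terms, a variant source, a blacklisted term."""
    rows = [
        ("E14", "diabetes"),
        ("E23", "diabetes insipidus"),
        ("D64", "anaemia caused by lead"),
        ("R50", "fever"),
        ("G43", "migraine"),
        ("J18", "pneumonia"),
        ("F20", "schizophrenia"),
        ("Z00", "status"),  # blacklisted below
    ]
    return build_dictionary(rows, specifiers=["caused by"], blacklist=["status"])


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mined cohort shared by invariant tests (deterministic)."""
    sdict = make_dictionary(20, seed=42)
    config = CohortConfig(
        n_patients=120,
        prevalence={c: 0.15 for c in sdict.codes},
        seed=42,
    )
    notes, assigned, truth = make_cohort(config, sdict)
    dictionary = build_dictionary(sdict.term_table, default_specifiers(), default_blacklist())
    return {
        "sdict": sdict,
        "notes": notes,
        "assigned": assigned,
        "truth": truth,
        "dictionary": dictionary,
        "lexicons": default_lexicons(),
    }
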