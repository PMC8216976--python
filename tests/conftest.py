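"""Shared frozen expectations for the published pooled count tables.

``PRINTED`` maps (association_type, species, tide_phase) to the published
expected counts (1 dp), chi-square statistic (2 dp) and significance
annotation.  Combination keys read role-1 sex then role-2 sex (marker →
tracker for trails, bottom → top for towers).  The *E. radiata*
falling-tide trail table omits its FF expected because the source prints
no FF row (the count is inferred from the declared total).
"""

import pytest

PRINTED = {
    ("trail_following", "E. malaccana", "rising"): {
        "expected": {"FM": 31.6, "MM": 34.4, "MF": 31.6, "FF": 28.4},
        "chi2": 58.79,
        "annotation": "< .001",
    },
    ("trail_following", "E. malaccana", "falling"): {
        "expected": {"FM": 30.1, "MM": 29.4, "MF": 30.1, "FF": 30.4},
        "chi2": 3.75,
        "annotation": "n.s.",
    },
    ("trail_following", "E. radiata", "rising"): {
        "expected": {"FM": 29.7, "MM": 22.8, "MF": 29.7, "FF": 37.8},
        "chi2": 45.72,
        "annotation": "< .001",
    },
    ("trail_following", "E. radiata", "falling"): {
        "expected": {"FM": 30.0, "MM": 26.0, "MF": 30.0},
        "chi2": 0.20,
        "annotation": "n.s.",
    },
    ("tower", "E. malaccana", "before_rising"): {
        "expected": {"FM": 10.3, "MM": 8.7, "MF": 10.3, "FF": 11.7},
        "chi2": 55.58,
        "annotation": "< .001",
    },
    ("tower", "E. malaccana", "after_falling"): {
        "expected": {"FM": 16.1, "MM": 15.9, "MF": 16.1, "FF": 15.9},
        "chi2": 8.25,
        "annotation": "< .05",
    },
    ("tower", "E. radiata", "before_rising"): {
        "expected": {"FM": 10.1, "MM": 9.9, "MF": 10.1, "FF": 9.9},
        "chi2": 88.79,
        "annotation": "< .001",
    },
    ("tower", "E. radiata", "after_falling"): {
        "expected": {"FM": 10.7, "MM": 13.8, "MF": 10.7, "FF": 7.8},
        "chi2": 26.37,
        "annotation": "< .001",
    },
}


@pytest.fixture(scope="session")
def field_tables():
    from highshore import load_field_tables

    return load_field_tables()
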