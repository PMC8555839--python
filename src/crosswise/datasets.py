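"""Built-in data: the street-crossing faking study.

The study asked university students (N = 1,946) whether they had crossed the
street on a "Don't Walk" sign in plain sight of a child within the past 12
months, in a 2x2 between-subjects design crossing questioning technique
(direct question vs crosswise model, p = .158) with instruction (honest vs
fake good).

Answer counts were reconstructed by inverting the published percentage
estimates at the published group sizes and verifying that neighbouring
integer counts fail to reproduce the printed rounding; they are exact up to
that rounding.  The Likert summary targets are the published per-condition
means and standard errors of the three experience items and parameterize the
synthetic respondent simulator.
"""

from __future__ import annotations

from .design import CwmDesign
from .mpt import CountTable

__all__ = [
    "RANDOMIZATION_P",
    "STREET_CROSSING_DESIGN",
    "GROUP_SIZES",
    "street_crossing_counts",
    "LIKERT_TARGETS",
]

#: prevalence of being born in November or December (official birth statistics)
RANDOMIZATION_P = 0.158

STREET_CROSSING_DESIGN = CwmDesign(
    p=RANDOMIZATION_P, source="German official birth statistics (Nov/Dec births)"
)

#: respondents per experimental condition
GROUP_SIZES = {
    "dq_honest": 334,
    "dq_fake_good": 326,
    "cwm_honest": 637,
    "cwm_fake_good": 649,
}

_CONDITION_META = {
    "dq_honest": {"technique": "DQ", "instruction": "honest"},
    "dq_fake_good": {"technique": "DQ", "instruction": "fake_good"},
    "cwm_honest": {"technique": "CWM", "instruction": "honest"},
    "cwm_fake_good": {"technique": "CWM", "instruction": "fake_good"},
}


def street_crossing_counts() -> CountTable:
    """Reconstructed answer frequencies of the street-crossing study.

    DQ conditions count "true" (admitting the behaviour); CWM conditions
    count "both_none" (both statements true or both false).
    """
    return CountTable(
        {
            "dq_honest": {"true": 117, "false": 334 - 117},
            "dq_fake_good": {"true": 51, "false": 326 - 51},
            "cwm_honest": {"both_none": 338, "exactly_one": 637 - 338},
            "cwm_fake_good": {"both_none": 360, "exactly_one": 649 - 360},
        },
        meta=_CONDITION_META,
    )


#: published per-condition mean (SE) of the three 7-point experience items
LIKERT_TARGETS = {
    "sensitivity": {
        "dq_honest": (5.27, 0.08),
        "cwm_honest": (5.28, 0.07),
        "dq_fake_good": (5.07, 0.09),
        "cwm_fake_good": (5.14, 0.07),
    },
    "confidentiality": {
        "dq_honest": (4.66, 0.10),
        "cwm_honest": (4.78, 0.07),
        "dq_fake_good": (3.82, 0.12),
        "cwm_fake_good": (4.37, 0.08),
    },
    "ease": {
        "dq_honest": (3.10, 0.11),
        "cwm_honest": (3.71, 0.07),
        "dq_fake_good": (2.83, 0.11),
        "cwm_fake_good": (3.73, 0.07),
    },
}
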