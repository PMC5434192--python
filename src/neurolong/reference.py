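"""Published demographic summaries of the motivating trial, as fixtures.

These are the printed baseline tables of the two training arms (strategy-
based treatment, N = 31, vs knowledge-based active control, N = 29): count
tables for the categorical rows and mean/SD/n summaries for the continuous
ones.  They are inputs to the demographic battery, not results computed by
this package.
"""

from __future__ import annotations

from .behavior import GroupSummary

__all__ = [
    "GENDER_TABLE",
    "CIVILIAN_VETERAN_TABLE",
    "SEVERITY_TABLE",
    "INJURY_CAUSE_TABLE",
    "CURRENT_IQ",
    "PREMORBID_IQ",
]

#: male / female counts, rows = (treatment, control)
GENDER_TABLE = [[20, 11], [16, 13]]

#: civilian / veteran counts, rows = (treatment, control)
CIVILIAN_VETERAN_TABLE = [[20, 11], [20, 9]]

#: estimated initial injury severity (mild, moderate, severe)
SEVERITY_TABLE = [[21, 5, 5], [23, 1, 5]]

#: primary cause of injury
#: (blast, blunt force, fall, athletic, vehicle, combined)
INJURY_CAUSE_TABLE = [[3, 3, 3, 7, 9, 6], [5, 7, 3, 5, 6, 3]]

CURRENT_IQ = (GroupSummary(108.6, 9.5, 31), GroupSummary(113.3, 9.7, 29))
PREMORBID_IQ = (GroupSummary(109.6, 8.5, 31), GroupSummary(112.0, 8.5, 29))
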