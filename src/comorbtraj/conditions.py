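"""Canonical condition labels and ordering conventions.

The analysis tracks 16 common long-term conditions around one index
condition (heart failure by default).  ``TRANSITION_PRIORITY`` is the fixed
condition ordering used to break exact date ties deterministically when
picking the diagnosis immediately before/after the index event.
"""

from __future__ import annotations

INDEX_CONDITION = "heart_failure"

#: Tie-break priority for adjacent-diagnosis resolution (first wins).
TRANSITION_PRIORITY: tuple[str, ...] = (
    "dementia",
    "myocardial_infarction",
    "stroke",
    "copd",
    "peripheral_arterial_disease",
    "chronic_renal_failure",
    "atrial_fibrillation",
    "anaemia",
    "asthma",
    "thyroid_disease",
    "hypertension",
    "diabetes",
    "cancer",
    "obesity",
    "depression",
    "osteoarthritis",
)

COMORBIDITIES: tuple[str, ...] = TRANSITION_PRIORITY

#: Human-readable names for rendered tables.
DISPLAY_NAMES: dict[str, str] = {
    "heart_failure": "Heart failure",
    "myocardial_infarction": "Myocardial infarction",
    "asthma": "Asthma",
    "stroke": "Stroke",
    "obesity": "Obesity",
    "cancer": "Cancer",
    "chronic_renal_failure": "Chronic renal failure",
    "copd": "COPD",
    "dementia": "Dementia",
    "atrial_fibrillation": "Atrial fibrillation/flutter",
    "hypertension": "Primary hypertension",
    "anaemia": "Anaemia",
    "diabetes": "Diabetes",
    "depression": "Depression",
    "thyroid_disease": "Thyroid disease",
    "peripheral_arterial_disease": "Peripheral arterial disease",
    "osteoarthritis": "Osteoarthritis",
}


def priority_rank(condition: str) -> int:
    """Rank of *condition* in the tie-break priority list (0 = highest)."""
    try:
        return TRANSITION_PRIORITY.index(condition)
    except ValueError:
        return len(TRANSITION_PRIORITY)
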