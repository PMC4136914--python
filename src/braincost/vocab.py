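"""Controlled vocabulary for the 19 brain disorders and the three cost categories.

The disorder list follows the diagnostic grouping used in European
cost-of-disorders-of-the-brain studies: 10 mental and 9 neurological /
neurosurgical diagnostic groups.  Identifiers are stable snake_case keys;
display names are kept alongside for report tables.
"""

from __future__ import annotations

#: Cost categories of a societal-perspective cost-of-illness study.
#: ``healthcare``  - inpatient/outpatient care, drugs, procedures, devices.
#: ``nonmedical``  - informal care, adaptations, transportation.
#: ``indirect``    - production losses (human-capital approach).
CATEGORIES: tuple[str, ...] = ("healthcare", "nonmedical", "indirect")

MENTAL = "mental"
NEUROLOGICAL = "neurological"

#: disorder_id -> (group, display name)
DISORDERS: dict[str, tuple[str, str]] = {
    "addiction": (MENTAL, "Addiction"),
    "anxiety_disorders": (MENTAL, "Anxiety disorders"),
    "child_adolescent_disorders": (MENTAL, "Child/adolescent disorders"),
    "eating_disorders": (MENTAL, "Eating disorders"),
    "intellectual_disability": (MENTAL, "Intellectual disability"),
    "mood_disorders": (MENTAL, "Mood disorders"),
    "personality_disorders": (MENTAL, "Personality disorders"),
    "psychotic_disorders": (MENTAL, "Psychotic disorders"),
    "sleep_disorders": (MENTAL, "Sleep disorders"),
    "somatoform_disorders": (MENTAL, "Somatoform disorders"),
    "brain_tumor": (NEUROLOGICAL, "Brain tumor"),
    "dementia": (NEUROLOGICAL, "Dementia"),
    "epilepsy": (NEUROLOGICAL, "Epilepsy"),
    "headache": (NEUROLOGICAL, "Headache"),
    "multiple_sclerosis": (NEUROLOGICAL, "Multiple sclerosis"),
    "neuromuscular_disorders": (NEUROLOGICAL, "Neuromuscular disorders"),
    "parkinsons_disease": (NEUROLOGICAL, "Parkinson's disease"),
    "stroke": (NEUROLOGICAL, "Stroke"),
    "traumatic_brain_injury": (NEUROLOGICAL, "Traumatic brain injury"),
}

DISORDER_IDS: tuple[str, ...] = tuple(DISORDERS)
MENTAL_DISORDERS: tuple[str, ...] = tuple(d for d, (g, _) in DISORDERS.items() if g == MENTAL)
NEUROLOGICAL_DISORDERS: tuple[str, ...] = tuple(
    d for d, (g, _) in DISORDERS.items() if g == NEUROLOGICAL
)

assert len(DISORDER_IDS) == 19 and len(MENTAL_DISORDERS) == 10


def group_of(disorder_id: str) -> str:
    """Return ``"mental"`` or ``"neurological"`` for a disorder id."""
    return DISORDERS[disorder_id][0]


def display_name(disorder_id: str) -> str:
    return DISORDERS[disorder_id][1]
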