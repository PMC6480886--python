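"""The chronic-disease checklist of the pre-operative questionnaire.

The instrument asks "Have you ever been told by a doctor that you have any of
the following conditions?" and lists twelve conditions. Arthritis is on the
questionnaire (and counts toward the high-count exclusion) but is excluded
from agreement analyses by default, because arthritis is the indication for
the joint replacement itself and is reported by the overwhelming majority of
patients.
"""

# Canonical machine names, in questionnaire order.
CONDITIONS: tuple[str, ...] = (
    "heart_disease",
    "high_blood_pressure",
    "stroke",
    "leg_pain_poor_circulation",
    "lung_disease",
    "diabetes",
    "kidney_disease",
    "nervous_system_disease",
    "liver_disease",
    "cancer",
    "depression",
    "arthritis",
)

#: Conditions analysed for agreement (arthritis excluded).
ANALYSIS_CONDITIONS: tuple[str, ...] = tuple(
    c for c in CONDITIONS if c != "arthritis"
)

DISPLAY_NAMES: dict[str, str] = {
    "heart_disease": "Heart disease",
    "high_blood_pressure": "High blood pressure",
    "stroke": "Stroke",
    "leg_pain_poor_circulation": "Leg pain due to poor circulation",
    "lung_disease": "Lung disease",
    "diabetes": "Diabetes",
    "kidney_disease": "Kidney disease",
    "nervous_system_disease": "Diseases of the nervous system",
    "liver_disease": "Liver disease",
    "cancer": "Cancer",
    "depression": "Depression",
    "arthritis": "Arthritis",
}
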