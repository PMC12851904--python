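"""Published context of the Welsh rollout study that the design emulates.

These counts describe the source study population and are used only as
reference inputs for arithmetic consistency checks and for calibrating the
generator's default shares; none of the estimators read them.
"""

STUDY_COUNTS = {
    "total": 304_940,
    "female": 167_461,
    "male": 137_478,
    "unspecified_gender": 1,
    "no_cognitive_impairment": 282_557,
    "living_with_dementia": 14_350,
    "mci_events_9y": 20_712,
    "dementia_death_events_9y": 7_049,
    "frequent_attenders": 135_712,
}

#: vaccine uptake just right of the threshold, by study cohort
UPTAKE_RIGHT_LIMIT = {"no_cognitive_impairment": 0.459, "living_with_dementia": 0.287}
UPTAKE_LEFT_LIMIT = 0.0


def percentage(numerator: int, denominator: int, digits: int = 1) -> float:
    """Share as a percentage rounded to the printed precision."""
    return round(100.0 * numerator / denominator, digits)


def derived_shares() -> dict:
    """Key percentages implied by the published counts."""
    c = STUDY_COUNTS
    return {
        "female_share_pct": percentage(c["female"], c["total"]),
        "no_cognitive_impairment_share_pct": percentage(c["no_cognitive_impairment"], c["total"]),
        "living_with_dementia_share_pct": percentage(c["living_with_dementia"], c["total"]),
        "mci_incidence_pct": percentage(c["mci_events_9y"], c["no_cognitive_impairment"]),
        "dementia_death_incidence_pct": percentage(c["dementia_death_events_9y"],
                                                   c["living_with_dementia"]),
        "frequent_attender_share_pct": percentage(c["frequent_attenders"],
                                                  c["no_cognitive_impairment"]),
        "uptake_jump_pp": {k: round(100.0 * (v - UPTAKE_LEFT_LIMIT), 1)
                           for k, v in UPTAKE_RIGHT_LIMIT.items()},
    }
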