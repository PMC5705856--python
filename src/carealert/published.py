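"""Published aggregate counts from the pooled caregiver e-alert trials.

These are the group-level counts published for the pooled analysis of two
randomized trials of an online caregiver support system with (ALERT arm,
"CHESS+CR") and without (CONTROL arm, "CHESS-Only") automatic clinician
alerts for severe caregiver-reported symptoms.  Raw check-in data were
never deposited; these printed aggregates are the only public record and
serve as desk-scale inputs for the inference layer and as calibration
targets for the synthetic cohort defaults.

Count pairs are (x, n): threshold symptoms out of assessed symptoms, or
improved threshold symptoms out of threshold symptoms, per 2-month period.
Order within each pair of pairs is (CONTROL, ALERT).
"""

from __future__ import annotations

from .inference import TwoSampleCounts

#: Enrolled / reporting caregivers per period (CONTROL, ALERT).
CAREGIVERS_PER_PERIOD: dict[str, tuple[int, int]] = {
    "pretest": (117, 118),
    "month2": (101, 104),
    "month4": (96, 93),
    "month6": (88, 85),
    "month8": (78, 74),
    "month10": (72, 68),
    "month12": (65, 63),
}

#: Threshold symptoms / assessed symptoms, per period: ((x,n) CONTROL, (x,n) ALERT).
THRESHOLD_OF_ASSESSED: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "pretest": ((182, 1026), (184, 1056)),
    "month2": ((385, 2620), (212, 2380)),
    "month4": ((263, 1820), (83, 1240)),
    "month6": ((219, 1490), (74, 840)),
    "month8": ((133, 1140), (34, 550)),
    "month10": ((140, 910), (26, 390)),
    "month12": ((129, 830), (14, 350)),
    "total": ((1269, 8810), (443, 5750)),
}

#: Improved threshold symptoms / all threshold symptoms, per period.
IMPROVED_OF_THRESHOLD: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "month2": ((103, 385), (113, 212)),
    "month4": ((67, 263), (44, 83)),
    "month6": ((53, 219), (41, 74)),
    "month8": ((39, 133), (17, 34)),
    "month10": ((33, 140), (14, 26)),
    "month12": ((37, 129), (6, 14)),
    "total": ((332, 1269), (235, 443)),
}

#: Threshold-symptom decomposition of the 12-month totals (CONTROL, ALERT).
TRANSITION_TOTALS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "improved": ((332, 1269), (235, 443)),
    "same": ((805, 1269), (146, 443)),
    "worsened": ((132, 1269), (62, 443)),
}

#: Paired pretest / first-online-check-in subset (dyads with both).
PRETEST_VS_FIRST_CHECKIN: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "pretest": ((106, 684), (105, 645)),
    "first_checkin": ((108, 684), (70, 645)),
}

#: Caregivers ever reporting / total symptoms reported over 12 months.
REPORTING_CAREGIVERS: dict[str, tuple[int, int]] = {
    "CONTROL": (71, 8810),
    "ALERT": (68, 5750),
}

#: Caregivers with >= 2 check-ins out of those receiving the intervention.
TWICE_REPORTERS: tuple[tuple[int, int], tuple[int, int]] = ((71, 107), (68, 110))


def counts(table: dict, key: str) -> TwoSampleCounts:
    """TwoSampleCounts for one row of a published table (CONTROL vs ALERT)."""
    (x1, n1), (x2, n2) = table[key]
    return TwoSampleCounts(x1, n1, x2, n2, label1="CONTROL", label2="ALERT")
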