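"""Hand-transcribed decision table, written independently of the engine.

Each entry maps (age_band, weight_status, core_risk, disorder, obese_parent)
to (recommendation, meal_plan, target, goal, review_months, inferred).  The
transcription follows the five-step pathway prose directly, cell by cell,
so the engine can be checked against it by exhaustive enumeration.
"""

from itertools import product

REFER = ("refer", "none", "child", "none", 3, False)


def expected_outcome(age_band, status, risk, dis, obp):
    if age_band == "over15" or status == "underweight":
        return REFER

    if status == "normal":
        review = 6 if (dis or obp) else 12
        if risk == "lower":
            return ("R1", "none", "child", "none", review, False)
        rec = {(False, False): "R1", (False, True): "R2",
               (True, False): "R3", (True, True): "R4"}[(dis, obp)]
        target = "family" if rec in ("R2", "R4") else "child"
        return (rec, "none", target, "none", review, False)

    review = 3 if (dis or obp) else 6
    rec = {(False, False): "R1", (False, True): "R2",
           (True, False): "R3", (True, True): "R4"}[(dis, obp)]
    target = "family" if rec in ("R2", "R4") else "child"

    if status == "overweight" or (status == "obese" and age_band == "y2_5"):
        plan = "MP2" if dis else "MP1"
        return (rec, plan, target, "maintenance", review, False)

    if status == "obese" and age_band == "y6_15":
        plan = "MP4" if dis else "MP3"
        inferred = not dis and not obp
        return (rec, plan, target, "mild_loss", review, inferred)

    # obese under-2: outside the printed pathway
    return REFER


def all_valid_states():
    """Every valid element of the finite state space."""
    for age_band, status, dis, obp in product(
        ("under2", "y2_5", "y6_15", "over15"),
        ("underweight", "normal", "overweight", "obese"),
        (False, True),
        (False, True),
    ):
        risks = ("lower", "higher") if status == "normal" else ("not_applicable",)
        for risk in risks:
            yield age_band, status, risk, dis, obp
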