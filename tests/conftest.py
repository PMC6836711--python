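import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from screenrank.records import BibRecord, ReviewSeries


def make_record(rid, title="a study title", abstract="an abstract text",
                iteration=0, label="A"):
    return BibRecord(rid, title, abstract, iteration, label)


@pytest.fixture
def two_iteration_series():
    """Hand-built series: iteration 0 trains, iteration 1 is the update.

    Positives all carry the token "coreset"; one iteration-1 record
    duplicates an iteration-0 title (a planted cross-iteration re-screen).
    """
    it0 = []
    fillers = [
        "plasma sodium randomized trial",
        "knee surgery cohort follow up",
        "infant sleep position survey",
        "migraine prophylaxis drug study",
        "wound care nursing audit",
        "asthma inhaler device comparison",
        "dietary score validation study",
        "stroke rehabilitation observational study",
        "hip fracture registry report",
    ]
    for i, t in enumerate(fillers):
        it0.append(make_record(f"a{i:02d}", t, f"background report about {t}", 0, "A"))
    for i in range(3):
        it0.append(
            make_record(
                f"ap{i}",
                f"coreset development for condition {i}",
                f"we developed a coreset using delphi methods round {i}",
                0,
                "Y",
            )
        )
    it1 = []
    for i, t in enumerate(
        ["renal dialysis adequacy audit", "vaccine uptake survey", "icu sedation trial",
         "cancer screening uptake study", "diabetes education program"]
    ):
        it1.append(make_record(f"b{i:02d}", t, f"new report about {t}", 1, "A"))
    # planted duplicate of a0 (same title, fresh id)
    it1.append(
        make_record("bdup", fillers[0], "background report about plasma", 1, "A")
    )
    for i in range(2):
        it1.append(
            make_record(
                f"bp{i}",
                f"new coreset published for area {i}",
                f"a coreset was agreed by consensus panel {i}",
                1,
                "Y",
            )
        )
    return ReviewSeries([it0, it1])
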