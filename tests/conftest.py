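import pytest

from pivasqc.rubric import default_rubric
from pivasqc.schema import Period, Submission, default_schema
from pivasqc.synthetic import default_reference_anchors


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def rubric():
    return default_rubric()


@pytest.fixture(scope="session")
def refs():
    """Anchors: A=1500 bags/day, bed=3.0, syringe=3.0, rate=2.0%, disp=0.70, err=0.002."""
    return default_reference_anchors()


def base_record() -> dict[str, str]:
    """A complete, audit-clean facility-quarter record (all 67 items, strings).

    Designed so every branch it triggers is easy to reason about by hand:
    m_daily = 800, consoles = 3 for 300 served beds, 8 pharmacists of 10
    staff, training ratio exactly 1.0, and so on.
    """
    return {
        "facility_id": "H-001",
        "year": "2021",
        "quarter": "1",
        # aspect A
        "A01": "Test Hospital",
        "A02": "1 Example Road",
        "A03": "L. Rep",
        "A04": "P. Director",
        "A05": "87112233",
        "A06": "R. Porter",
        "A07": "pharmacist in charge",
        "A08": "third-level A",
        "A09": "650032",
        "A10": "I. Director",
        "A11": "13800000001",
        "A12": "2016-03-01",
        # aspect B: area 350 m2 for m_daily 800; 3 consoles for 300 beds
        "B01": "350",
        "B02": "500",
        "B03": "13",
        "B04": "150",
        "B05": "1",
        "B06": "3",
        "B07": "2",
        "B08": "1",
        "B09": "30.0",
        "B10": "300",
        "B11": "300",
        "B12": "1",
        # aspect C: 10 trainings over 10 trainees -> ratio 1.0; 6/8 pharmacists
        "C01": "2",
        "C02": "5",
        "C03": "4",
        "C04": "300",
        "C05": "bachelor",
        "C06": "2",
        "C07": "5",
        "C08": "6",
        "C09": "supervising pharmacist",
        "C10": "6",
        # aspect D: m_daily = 600 + 200 = 800, temp rate 33%
        "D01": "72800",
        "D02": "20000",
        "D03": "10000",
        "D04": "450",
        "D05": "600",
        "D06": "500",
        "D07": "returning",
        "D08": "40",
        "D09": "30000",
        "D10": "68250",
        "D11": "30000",
        "D12": "12800",
        "D13": "90",
        "D14": "36400",
        "D15": "200",
        "D16": "1.37",
        "D17": "400",
        "D18": "30",
        "D19": "30",
        # aspect E: weekly cleaning, all filters maintained, two methods
        "E01": "13",
        "E02": "96.5",
        "E03": "98.0",
        "E04": "1",
        "E05": "1",
        "E06": "1",
        "E07": "95.0",
        "E08": "97.2",
        "E09": "5",
        "E10": "6",
        "E11": "ethanol, ultraviolet",
        # aspect F: 7 traceable kinds on 3 consoles -> ratio > 2
        "F01": (
            "drug dispensing scanner, label printing machine, infusion sorting machine, "
            "automatic dispensing robot, intelligent medicine cabinet, "
            "automatic labelling machine, infusion sealing machine"
        ),
        "F02": "1",
        "F03": "1",
    }


@pytest.fixture()
def record():
    return base_record()


def make_submission(schema, **overrides) -> Submission:
    from pivasqc.schema import parse_submission

    rec = base_record()
    rec.update({k: str(v) for k, v in overrides.items()})
    return parse_submission(rec, schema)


@pytest.fixture()
def submission(schema):
    return make_submission(schema)


def worst_submission(schema) -> Submission:
    """A submission that lands on the worst branch of all 20 indicators.

    Worst-branch points sum to 12: P3=2, W2=2, W3=1, W4=4, W8=1, W9=2,
    everything else 0.
    """
    m = 400  # below one-third of the 1500 reference
    d01 = m * 91
    return make_submission(
        schema,
        B01=50, B09=0,             # H1 fail (needs 300), H2 absent
        B05=0, B08=0, B12=1,       # 1 console for 300 beds -> H3 short
        C02=0, C07=0,              # training ratio 0 -> P1 worst
        C10=0, C06=8,              # all nurses -> P2 worst
        C09="pharmacist", C05="associate degree",  # P3 unqualified (2)
        D02=0, D03=0, D12=0, D11=0,  # W1: no drug classes dispensed (0)
        D05=m - 4, D15=4,          # m_daily=400 < 500; temp rate 1% -> W6 0
        D01=d01, D10=4 * 300 * 91,  # 4 bags/bed/day > 3 -> W3 above (1)
        D09=round(d01 / 4.0),      # 4 groups/syringe > 3 -> W4 above (4)
        D13=120,                   # W5 fail
        D04=900,                   # W7 above 800 (0)
        D14=d01 // 2, D06=round(0.03 * d01 // 2), D16=3.0,  # rate 3% > 2%
        D17=round(0.5 * 0.03 * d01 // 2),                   # disp 0.5 < 0.7 -> W8 worst (1)
        D08=50, D18=50, D19=50,    # err 150/36400 = 0.41% > 0.26% -> W9 worst (2)
        E01=1, E04=0, E05=0, E06=0, E11="ethanol",  # I1/I2/I3 worst
        F01="none", F02=0, F03=0,  # N1 0, N2 ratio 0
    )
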