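"""Shared fixtures: register fragments and handmade event streams."""

from datetime import date

import pytest

from icpc_audit import ProblemEvent, parse_register
from icpc_audit.refdata import d01_register


@pytest.fixture(scope="session")
def d01_reg():
    """The published 11-option register fragment for code D01."""
    return d01_register()


TOY_REGISTER_TSV = """\
# toy register: three codes, multi-option D01
D01\tAkutt abdomen
D01\tKolikksmerter
D01\tMagesmerter akutt
R81\tPneumoni
R81\tBakteriell pneumoni
T90\tDiabetes mellitus
"""


@pytest.fixture(scope="session")
def toy_register():
    return parse_register(TOY_REGISTER_TSV)


@pytest.fixture
def handmade_events():
    """10 events planted as 1 missing / 1 invalid code / 3 text mismatch / 5 valid."""

    def ev(code, text, year=1995, site="A"):
        return ProblemEvent(site=site, date=date(year, 6, 15), code=code, text=text)

    return [
        ev("   ", "Pneumoni"),                      # missing (whitespace-only)
        ev("Q99", "Akutt abdomen"),                 # code mismatch (Q not a chapter in use)
        ev("D01", "Magesmerter kronisk"),           # text mismatch
        ev("R81", "Lungebetennelse"),               # text mismatch
        ev("T90", "Sukkersyke"),                    # text mismatch
        ev("D01", "Akutt abdomen"),
        ev("D01", "  akutt   ABDOMEN "),            # valid after normalization
        ev("R81", "Pneumoni", year=2003),
        ev("R81", "Bakteriell pneumoni", year=2003),
        ev("t90 ", "Diabetes mellitus", year=2003),  # valid after code trimming/casing
    ]
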