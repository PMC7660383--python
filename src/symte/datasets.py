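"""Bundled data: the 1999-2017 US mass-shooting event table."""

from __future__ import annotations

from importlib.resources import files

from symte.io import read_events
from symte.preprocessing import EventList


def load_mass_shootings() -> EventList:
    """The packaged event list of 87 US mass shootings, 1999 through 2017.

    Compiled from the Washington Post mass-shootings database (incidents with
    four or more people killed, excluding robbery-, drug-, and domestic-
    related shootings); includes District of Columbia events.
    """
    path = files("symte").joinpath("data/mass_shootings_1999_2017.csv")
    return read_events(path)
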