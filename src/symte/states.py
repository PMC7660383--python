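"""US state and district codes used to resolve event and unit records."""

from __future__ import annotations

from symte.exceptions import StateResolutionError

US_STATES: dict[str, str] = {
    "AL": "Alabama", "AK": "Alaska", "AZ": "Arizona", "AR": "Arkansas",
    "CA": "California", "CO": "Colorado", "CT": "Connecticut", "DE": "Delaware",
    "FL": "Florida", "GA": "Georgia", "HI": "Hawaii", "ID": "Idaho",
    "IL": "Illinois", "IN": "Indiana", "IA": "Iowa", "KS": "Kansas",
    "KY": "Kentucky", "LA": "Louisiana", "ME": "Maine", "MD": "Maryland",
    "MA": "Massachusetts", "MI": "Michigan", "MN": "Minnesota",
    "MS": "Mississippi", "MO": "Missouri", "MT": "Montana", "NE": "Nebraska",
    "NV": "Nevada", "NH": "New Hampshire", "NJ": "New Jersey",
    "NM": "New Mexico", "NY": "New York", "NC": "North Carolina",
    "ND": "North Dakota", "OH": "Ohio", "OK": "Oklahoma", "OR": "Oregon",
    "PA": "Pennsylvania", "RI": "Rhode Island", "SC": "South Carolina",
    "SD": "South Dakota", "TN": "Tennessee", "TX": "Texas", "UT": "Utah",
    "VT": "Vermont", "VA": "Virginia", "WA": "Washington",
    "WV": "West Virginia", "WI": "Wisconsin", "WY": "Wyoming",
}

#: non-state units that may appear in event records
DISTRICTS: dict[str, str] = {"DC": "District of Columbia"}

_ALL = {**US_STATES, **DISTRICTS}
_NAME_TO_CODE = {name.lower(): code for code, name in _ALL.items()}
_NAME_TO_CODE["washington dc"] = "DC"
_NAME_TO_CODE["washington, d.c."] = "DC"


def resolve_state(value: str, context: str = "") -> str:
    """Resolve a two-letter code or full name to a canonical code.

    Raises :class:`StateResolutionError` naming ``context`` on failure.
    """
    token = str(value).strip()
    if token.upper() in _ALL:
        return token.upper()
    code = _NAME_TO_CODE.get(token.lower())
    if code is None:
        where = f" in {context}" if context else ""
        raise StateResolutionError(f"cannot resolve state {value!r}{where}")
    return code
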