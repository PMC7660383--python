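"""Exception hierarchy."""


class SymteError(Exception):
    """Base class for package errors."""


class AlignmentError(SymteError, ValueError):
    """Series have mismatched lengths or calendar indices."""


class CapacityError(SymteError, ValueError):
    """Too many conditioning processes for the available series length."""


class NormalizationError(SymteError, ValueError):
    """A probability mass function does not sum to one."""


class EmptyHistogramError(SymteError, ValueError):
    """A histogram with no observations cannot yield an entropy."""


class StateResolutionError(SymteError, ValueError):
    """A record references a unit that cannot be resolved."""


class CalendarGapError(SymteError, ValueError):
    """A monthly series has a missing or duplicated month."""
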