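"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`AdspectError`
so callers can distinguish pipeline contract failures from programming bugs.
"""


class AdspectError(Exception):
    """Base class for all adspect errors."""


class SpecificationError(AdspectError, ValueError):
    """A cohort or effect specification violates its invariants."""


class ParameterError(AdspectError, ValueError):
    """An operation was called with out-of-range parameters."""


class EpochingError(AdspectError, ValueError):
    """A requested epoch window falls outside the recording."""


class MappingError(AdspectError, KeyError):
    """A region's electrode is missing from the channel list."""


class DegenerateInputError(AdspectError, ValueError):
    """Input is structurally valid but numerically degenerate (e.g. all-zero power)."""


class AlignmentError(AdspectError, ValueError):
    """Two tables that must share subjects or keys do not."""


class DesignError(AdspectError, ValueError):
    """The group design cannot support the requested statistic."""
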