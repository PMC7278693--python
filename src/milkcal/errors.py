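"""Exception hierarchy.

Everything user-facing derives from :class:`MilkcalError` so the CLI can map
any anticipated failure to exit code 2 while genuine bugs still traceback.
"""


class MilkcalError(Exception):
    """Base class for all anticipated errors."""


class FormatError(MilkcalError):
    """Malformed input file or code string (ragged rows, bad units, ...)."""


class InvariantError(MilkcalError):
    """A domain-type invariant would be violated (duplicate IDs, negative
    concentration, non-monotone axis, ...)."""


class DegenerateSpectrumError(MilkcalError):
    """A spectrum with no variance (or a zero regression slope) reached an
    operator that needs to divide by it."""


class FitError(MilkcalError):
    """Model fitting impossible under the given data/parameters."""
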