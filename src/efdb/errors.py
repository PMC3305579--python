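"""Exception hierarchy."""


class EfdbError(Exception):
    """Base class for all package errors."""


class SeriesError(EfdbError):
    """An expression series violates a structural precondition."""


class FormatError(EfdbError):
    """A flat file is malformed; message carries the offending line number."""


class PlatformMismatchError(EfdbError):
    """Profiles, indexes and databases from different platforms were mixed."""
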