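"""Exception hierarchy for fbgscan."""


class FBGScanError(Exception):
    """Base class for all fbgscan errors."""


class SequenceValidationError(FBGScanError):
    """A sequence contains characters outside the accepted protein alphabet."""


class BoundaryError(FBGScanError):
    """An interval or position falls outside the sequence it refers to."""


class ConfigError(FBGScanError):
    """Packaged data or user configuration is missing or inconsistent."""


class AlignmentError(FBGScanError):
    """Invalid alignment input or alignment/annotation mismatch."""


class MutationError(FBGScanError):
    """A mutation edit does not apply to the current sequence."""


class ScanError(FBGScanError):
    """A domain cannot be scanned (e.g. it does not look like an FBG domain)."""
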