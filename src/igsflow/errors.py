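"""Exception hierarchy shared across the package."""


class IgsflowError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IgsflowError):
    """A file does not conform to its declared format."""


class PairingError(FormatError):
    """Paired FASTQ files disagree on record count or read ids."""


class AlignmentError(IgsflowError):
    """Sequences expected to be aligned have unequal lengths or bad symbols."""


class ManifestError(IgsflowError):
    """Sample manifest is malformed or internally inconsistent."""


class ConfigError(IgsflowError):
    """Simulation or pipeline configuration violates its invariants."""
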