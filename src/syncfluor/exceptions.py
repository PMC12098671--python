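"""Exception hierarchy; the CLI maps these onto its documented exit codes."""


class SyncfluorError(Exception):
    """Base class for all package errors."""


class DataError(SyncfluorError):
    """Bad or missing input data: files, parse failures, invalid config."""


class SpectrumFormatError(DataError):
    """A spectrum or EEM file violates the documented CSV schema."""


class GridError(DataError):
    """Wavelength grids inconsistent, incomplete, or non-overlapping."""


class ConfigError(DataError):
    """Run configuration violates its invariants."""


class NumericError(SyncfluorError):
    """A computation cannot proceed (degenerate fit, unresolvable channels)."""


class UnresolvableChannelsError(NumericError):
    """No measurement wavelength satisfies the sensitivity floor."""
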