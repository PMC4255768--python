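"""Exception hierarchy.

``ConfigurationError`` covers invalid parameters supplied by the caller;
``DataError`` covers malformed or uninterpretable input data, with the
narrower ``MeasurementError`` / ``SaturationError`` for assay readouts that
cannot be converted to a copy number, and ``HomoplasyError`` for marker
presence/absence patterns incompatible with a single insertion origin.
"""


class CnvBlockError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CnvBlockError):
    """Invalid configuration or parameter value."""


class DataError(CnvBlockError):
    """Malformed, inconsistent, or uninterpretable input data."""


class MeasurementError(DataError):
    """An assay run that cannot yield a copy-number estimate."""


class SaturationError(MeasurementError):
    """A digital-PCR read with no negative droplets (lambda unbounded)."""


class HomoplasyError(DataError):
    """Marker presence/absence incompatible with a single insertion event."""
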