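"""Exception hierarchy for the rededge pipeline.

Each error names the pipeline stage contract it enforces so CLI logs can
point at the offending input rather than a bare ValueError.
"""


class RededgeError(Exception):
    """Base class for all package errors."""


class MetadataError(RededgeError):
    """Wavelength metadata missing, unsorted, or inconsistent with the data."""


class FormatError(RededgeError):
    """File contents do not match the declared on-disk format."""


class BandLookupError(RededgeError, KeyError):
    """No band within tolerance of a requested wavelength, or unknown band id."""


class CoverageError(RededgeError):
    """Too few source samples/bands to resample or integrate a spectral window."""


class DegenerateDataError(RededgeError):
    """Predictor or target carries no information (constant, all-zero, empty)."""


class UsageError(RededgeError):
    """Mismatched shapes, axes, units, or mutually exclusive options."""
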