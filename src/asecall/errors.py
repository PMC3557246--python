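"""Exception hierarchy shared across the package."""


class AsecallError(Exception):
    """Base class for all package-specific errors."""


class EmptySpectrumError(AsecallError):
    """Both allele peaks are zero; no allelic fraction can be formed."""


class QCFailureError(AsecallError):
    """No replicate of a measurement passed quality control."""


class NonInformativeGenotypeError(AsecallError):
    """gDNA genotype is homozygous; alleles cannot be distinguished."""


class DegenerateScaleError(AsecallError):
    """Scale estimate is zero; an outlier region cannot be formed."""


class CalibrationError(AsecallError):
    """Standard series is unusable for curve fitting or normalization."""


class SchemaError(AsecallError):
    """An input table does not match its documented schema."""


class AlleleSeparationError(AsecallError):
    """No informative phasing SNP; clones cannot be split by allele."""
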