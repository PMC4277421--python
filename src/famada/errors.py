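"""Exception hierarchy for famada.

All domain errors derive from :class:`FamadaError` so callers (and the CLI)
can distinguish malformed input / degenerate configuration from programming
errors.
"""


class FamadaError(Exception):
    """Base class for all famada domain errors."""


class PedigreeStructureError(FamadaError):
    """Invalid pedigree: cycles, half-parented individuals, duplicate ids."""


class PhaseError(FamadaError):
    """Genotypes are not phased where phase is required."""


class ConsistencyError(FamadaError):
    """Pedigree, genotype and trait sources disagree on membership."""


class UnsupportedSiteError(FamadaError):
    """Site cannot be represented (e.g. multi-allelic)."""


class DegenerateTraitError(FamadaError):
    """Trait carries no usable variation after covariate adjustment."""


class EstimationError(FamadaError):
    """Covariate adjustment model cannot be fit (rank deficiency)."""


class ConfigurationError(FamadaError):
    """Invalid analysis or simulation configuration."""


class EnumerationSizeError(FamadaError):
    """Pedigree too large for exhaustive transmission enumeration."""


class NoTestError(FamadaError):
    """No valid (polymorphic-in-founders) site to test."""


class CalibrationError(FamadaError):
    """Trait-model calibration impossible (e.g. non-segregating causal site)."""
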