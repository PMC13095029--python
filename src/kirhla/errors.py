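"""Exception hierarchy shared across the pipeline stages."""


class KirhlaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(KirhlaError, ValueError):
    """Invalid simulation or run configuration (probability out of range, n < 1, ...)."""


class InputError(KirhlaError, ValueError):
    """Malformed numeric input (dosage outside [0,2], posteriors not summing to 1, ...)."""


class SchemaError(KirhlaError, ValueError):
    """A delimited table does not match its documented dialect."""


class FormatError(KirhlaError, ValueError):
    """A HAPS/SAMPLE haplotype file violates the Oxford format conventions."""


class UnclassifiedAlleleError(KirhlaError, ValueError):
    """An HLA-C allele family belongs to neither the C1 nor the C2 ligand group."""


class MendelianError(KirhlaError, ValueError):
    """A mother-offspring genotype pair is Mendelian-inconsistent where consistency is required."""


class DegenerateDesignError(KirhlaError, ValueError):
    """A required genetic regressor is constant across the design rows."""


class FitError(KirhlaError, RuntimeError):
    """Mixed-model estimation failed (singular covariance or non-convergence)."""
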