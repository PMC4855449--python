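"""Exception hierarchy for aimix.

All package-specific failures derive from :class:`AimixError` so callers can
catch one base class at CLI boundaries.
"""


class AimixError(Exception):
    """Base class for all aimix errors."""


class PanelFormatError(AimixError):
    """A panel/genotype file is structurally malformed (missing columns, bad header)."""


class ValidationError(AimixError):
    """A value violates a domain invariant (frequency out of [0,1], bad dosage...)."""


class OrientationError(AimixError):
    """Allele orientation conflicts between two sources for the same SNP."""


class NoDataError(AimixError):
    """An individual has no non-missing genotype to estimate from."""


class DegenerateInformationError(AimixError):
    """The 2x2 information matrix is singular or near-singular; variances are
    undefined.  This is the explicit form of the method's internal warning
    signal: when a panel carries no information for a contrast, the standard
    errors blow up rather than the point estimate silently looking fine."""


class SelectionError(AimixError):
    """AIM selection cannot build a balanced panel (a contrast has no survivors)."""


class ConfigError(AimixError):
    """A simulation or selection configuration is invalid or infeasible."""
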