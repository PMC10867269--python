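"""Exception hierarchy for mrmediation.

All package errors derive from :class:`MRMediationError` so callers can
catch broadly; the CLI maps subclasses onto distinct exit codes.
"""


class MRMediationError(Exception):
    """Base class for all mrmediation errors."""


class FormatError(MRMediationError):
    """A summary-statistics file is structurally unreadable (e.g. a
    required column is missing from the header)."""


class ValidationError(MRMediationError):
    """Record-level content violates an invariant (non-ACGT allele,
    non-positive SE, duplicated SNP id, ...). The message carries
    row-level diagnostics."""


class ConfigError(MRMediationError):
    """A scenario or run configuration violates its invariants."""


class EmptyPanelError(MRMediationError):
    """Harmonization or instrument filtering left no usable SNPs."""


class InsufficientInstrumentsError(MRMediationError):
    """An estimator was handed fewer SNPs than it needs."""


class CollinearityError(MRMediationError):
    """The multivariable instrument-effect matrix is rank deficient."""


class UnitError(MRMediationError):
    """An effect was supplied on the wrong scale (e.g. an odds ratio
    where a log-odds coefficient is required)."""


class MissingLDError(MRMediationError):
    """A SNP lacks position (or LD) information in the reference."""
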