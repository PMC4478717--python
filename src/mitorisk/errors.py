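"""Exception hierarchy shared across the pipeline."""


class MitoriskError(Exception):
    """Base class for all package errors."""


class TreeStructureError(MitoriskError):
    """Cycle, multiple roots, or disconnected haplogroup tree."""


class MutationParseError(MitoriskError):
    """Mutation token does not match the [ACGT]<pos>[ACGT][!] grammar."""


class ConsistencyError(MitoriskError):
    """An edge mutation's source allele disagrees with the parent state."""


class ConfigurationError(MitoriskError):
    """Mutually inconsistent inputs (panels, files, settings)."""


class DataError(MitoriskError):
    """Invalid values inside an otherwise well-formed input."""


class EmptyPanelError(MitoriskError):
    """Quality filtering removed every locus."""


class EmptyCohortError(MitoriskError):
    """Quality filtering removed every sample."""


class FitError(MitoriskError):
    """The survival model could not be fitted (e.g. separation)."""
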