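"""Exception hierarchy shared across the package."""


class PolydivError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(PolydivError):
    """Sequences violate an alignment invariant (length mismatch, bad characters)."""


class ManifestError(PolydivError):
    """Locus manifest is inconsistent with the FASTA contents."""


class AnnotationError(PolydivError):
    """Coding annotation is invalid (overlapping segments, internal stop codon)."""


class UndefinedStatisticError(PolydivError):
    """A statistic is undefined for the given input (e.g. zero denominator).

    Most summary-level code reports undefined statistics as ``None``/NaN
    instead of raising; this error is for direct calls where silently
    returning a value would be misleading.
    """


class SaturationError(PolydivError):
    """Jukes-Cantor correction is undefined (observed difference >= 0.75)."""


class FitError(PolydivError):
    """A likelihood optimisation failed to converge after all restarts."""
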