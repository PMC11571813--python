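"""Exception hierarchy for the utag pipeline."""


class UTagError(Exception):
    """Base class for all utag errors."""


class ParameterError(UTagError, ValueError):
    """Invalid simulation or analysis parameters."""


class FormatError(UTagError, ValueError):
    """Malformed sequence or file content."""


class AnnotationError(UTagError, ValueError):
    """Unknown chromosome or inconsistent gene annotation."""


class NormalizationError(UTagError, ValueError):
    """Matrix cannot be RPM-normalized (e.g. zero total)."""


class QCError(UTagError, ValueError):
    """No replicate passed quality control; message lists per-replicate stats."""


class InsufficientDataError(UTagError, ValueError):
    """Too few genes/observations for the requested statistic."""


class UndefinedReliabilityError(UTagError, ValueError):
    """All correlations in the 4..13 block are missing (e.g. dead-enzyme control)."""


class UndefinedCompositionError(UTagError, ValueError):
    """Amino-acid composition requested over an empty residue mask."""


class ContractError(UTagError, ValueError):
    """Caller violated a function contract (mismatched lengths, inconsistent counts)."""
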