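"""Exception hierarchy for the QA pipeline.

Every stage raises a subclass of :class:`QAError`, so the pipeline driver can
catch one type, attach the stage name, and turn the failure into an overall
FAIL verdict instead of a traceback.
"""


class QAError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(QAError):
    """An input file does not conform to its documented format."""


class IntegrityError(QAError):
    """An input parses but violates a semantic invariant (e.g. time order)."""


class UsageError(QAError):
    """The caller supplied arguments that the operation cannot accept."""


class PairingError(QAError):
    """Plan and delivered segments cannot be put into correspondence.

    This is itself a QA finding: a delivery with missing or extra segments
    fails verification before any dosimetric comparison runs.
    """


class UnsupportedPlanError(QAError):
    """The RT Plan uses features outside the step-and-shoot static-gantry model."""


class GeometryMismatchError(QAError):
    """The plan or log does not match the configured machine geometry."""


class GenerationError(QAError):
    """A synthetic plan/log specification is infeasible."""
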