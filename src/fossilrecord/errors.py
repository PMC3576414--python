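"""Exception types shared across the package."""


class FossilRecordError(Exception):
    """Base class for all package errors."""


class FormatError(FossilRecordError):
    """A file does not conform to the expected dialect."""


class ValidationError(FossilRecordError):
    """Input data violate a documented invariant (e.g. alt > total)."""


class PhylogenyConflictError(FossilRecordError):
    """The clone x mutation matrix does not admit a perfect phylogeny.

    Carries the :class:`~fossilrecord.genealogy.ConflictReport` so callers
    can inspect (and optionally drop) the offending mutation pairs.
    """

    def __init__(self, report):
        self.report = report
        super().__init__(
            f"clone matrix admits no perfect phylogeny: "
            f"{len(report.conflicts)} conflicting mutation pair(s)"
        )
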