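"""Exception hierarchy for bsamap.

All package-raised errors derive from :class:`BsamapError` so callers can
catch everything from this package with a single ``except`` clause.
"""


class BsamapError(Exception):
    """Base class for all bsamap errors."""


class FormatError(BsamapError):
    """A file is structurally malformed (missing columns, bad header, ...)."""


class ValidationError(BsamapError):
    """A value violates a domain invariant (negative count, bad allele, ...)."""


class InputError(BsamapError):
    """Inputs violate an operation precondition (unsorted sites, unknown chromosome, ...)."""
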