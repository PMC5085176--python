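"""Exception hierarchy.

``DataValidationError`` marks problems with user-supplied data (bad FASTA,
annotation mismatches, malformed tables); the command-line layer maps it to
a distinct exit code so scripted pipelines can tell bad input from bugs.
"""


class CarbonsiteError(Exception):
    """Base class for package errors."""


class DataValidationError(CarbonsiteError):
    """User-supplied data failed validation."""


class LeakageError(CarbonsiteError):
    """The cross-validation leakage audit failed (synthetic sample or
    train/test overlap detected in a test fold)."""


class SelfConsistencyError(CarbonsiteError):
    """A query window's center residue does not match the model it was
    scored with.  A K-centered window must be scored by the K-trained
    model, and so on for P, R and T."""
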