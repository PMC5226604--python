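"""Exception hierarchy shared by all raspdx modules.

Two failure classes are distinguished because the command-line layer maps
them to distinct exit codes: data that violates a documented invariant is a
:class:`ValidationError` (exit 2), while calling an operation outside its
stated contract (wrong scale tag, mismatched lengths, cohort mismatch) is a
:class:`ContractError` (exit 3).
"""

from __future__ import annotations


class RaspdxError(Exception):
    """Base class for all raspdx-specific errors."""


class ValidationError(RaspdxError):
    """Input data violates a documented invariant (exit code 2)."""


class FormatError(ValidationError):
    """A file could not be parsed as the declared format."""


class ContractError(RaspdxError):
    """An operation was invoked outside its stated contract (exit code 3)."""
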