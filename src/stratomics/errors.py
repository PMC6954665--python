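"""Exception hierarchy.

``InputError`` covers everything a user can fix (malformed files, schema
violations, range errors); it maps to CLI exit code 1. Any other exception
escaping the pipeline is an internal error (exit code 2).
"""


class StratomicsError(Exception):
    """Base class for all package-raised errors."""


class InputError(StratomicsError):
    """Invalid or inconsistent user input (fatal parse/schema/range errors)."""
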