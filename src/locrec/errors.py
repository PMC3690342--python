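"""Exception hierarchy.

Distinct classes let the command line map failure modes onto distinct
exit codes: malformed files (:class:`FormatError`), bad values such as an
unknown compartment label or method token (:class:`VocabularyError`,
plain :class:`ValueError`), and simulator misconfiguration
(:class:`ConfigError`).
"""

from __future__ import annotations


class LocrecError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(LocrecError):
    """A file does not have the expected structure (e.g. missing columns)."""


class VocabularyError(LocrecError, ValueError):
    """A compartment label is outside the controlled vocabulary."""


class ConfigError(LocrecError, ValueError):
    """A simulator configuration value is invalid."""
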