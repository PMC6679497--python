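"""Structured exceptions and warnings.

Every error and warning carries a machine-checkable ``code`` string so that
callers (and tests) can dispatch on failure class instead of parsing prose.
"""

from __future__ import annotations

import warnings


class SynscreenError(Exception):
    """Base class; ``code`` identifies the failure class."""

    code = "generic"

    def __init__(self, message: str, code: str | None = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class InputFormatError(SynscreenError):
    code = "io.format"


class InputIOError(SynscreenError):
    code = "io.unreadable"


class DegenerateNetworkError(SynscreenError):
    code = "network.degenerate"


class DomainError(SynscreenError):
    code = "domain.invalid"


class UndefinedScoreError(SynscreenError):
    code = "score.undefined"


class OntologyError(SynscreenError):
    code = "ontology.invalid"


class MissingAnnotationError(SynscreenError):
    code = "ontology.unannotated"


class ConfigError(SynscreenError):
    code = "config.invalid"


class SynscreenWarning(UserWarning):
    """Base warning; instances carry a ``code`` attribute."""

    def __init__(self, message: str, code: str = "generic"):
        super().__init__(message)
        self.code = code


def warn(message: str, code: str) -> None:
    """Emit a :class:`SynscreenWarning` with a structured code."""
    warnings.warn(SynscreenWarning(message, code), stacklevel=3)
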