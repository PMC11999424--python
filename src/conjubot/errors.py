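"""Exception hierarchy.

Every error carries a short machine-readable ``reason`` code alongside the
human message, so callers (and tests) can distinguish e.g. a capacity
violation from an unresolved reference without string matching.
"""

from __future__ import annotations


class ConjubotError(Exception):
    """Base class for all package errors."""

    def __init__(self, reason: str, message: str) -> None:
        self.reason = reason
        super().__init__(f"[{reason}] {message}")


class DesignError(ConjubotError):
    """Invalid experiment design (parse, duplicate, reference, capacity, mode)."""


class ModelError(ConjubotError):
    """Invalid labware/deck model request."""


class PlanError(ConjubotError):
    """Protocol compilation failure (capacity, volume, empty)."""


class ExecError(ConjubotError):
    """Virtual execution failure (no_tip, overdraw, overflow, tip_capacity, ...)."""


class ArtifactError(ConjubotError):
    """Output rendering failure (e.g. missing user identity)."""


class StatsError(ConjubotError):
    """Invalid input to an efficiency statistic."""
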