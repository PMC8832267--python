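"""Shared helpers: exceptions, reporting-precision rounding, file hashing."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal


class VapenetError(Exception):
    """Base class for all package errors."""


class ValidationError(VapenetError):
    """Invalid value for a domain object (bad probability vector, duplicate label...)."""


class SchemaError(VapenetError):
    """Malformed serialized input (missing field, bad JSON); carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StageError(VapenetError):
    """Operation applied to a corpus at the wrong deduplication stage."""


class InfeasibleConfigError(VapenetError):
    """Generator configuration asks for more results than the video pool holds."""


class DegenerateInputError(VapenetError):
    """Input too small or too empty for the requested statistic."""


class ConfigError(VapenetError):
    """Unknown stop list, lemmatizer backend, ruleset or output format name."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero, the convention used for all
    reported percentages and table values (2.5 -> 3, 29.65 -> 29.7)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
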