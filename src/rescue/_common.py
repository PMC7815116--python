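"""Shared alphabet constants and exception types."""

from __future__ import annotations

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Default inference alphabet: 20 amino acids plus an explicit gap state.
#: Ambiguous letters (X and the rarer B/Z/U/O) are folded into the gap state.
PROTEIN_ALPHABET = AA20 + GAP


class RescueError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RescueError):
    """A file or in-memory object violates the expected format."""


class ParameterError(RescueError, ValueError):
    """A parameter is outside its documented range."""


class NumericalError(RescueError):
    """An optimization or score became non-finite."""


class UndefinedScoreError(RescueError):
    """A score is mathematically undefined for the given inputs (e.g. crs
    with a native coupling strength of zero)."""


def default_alphabet(q: int) -> str:
    """Canonical state alphabet for a q-state model.

    q = 21 yields the 20 amino acids plus gap; q <= 20 yields the first q
    amino-acid letters in the canonical order.
    """
    if q == 21:
        return PROTEIN_ALPHABET
    if 2 <= q <= 20:
        return AA20[:q]
    raise ParameterError(f"no default alphabet for q={q}")
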