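"""Canonical motif algebra for microsatellite repeat units.

A repeat unit of 2-6 bp is read equivalently from either strand and from any
phase of the tandem array, so a motif *class* is the orbit of a unit under
cyclic rotation and reverse complementation.  The class representative
("canonical motif") is the lexicographically smallest member of the orbit;
this convention puts the smaller strand first, so dinucleotide classes are
written AC, AG, AT, CG and e.g. GT normalises to AC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

from .errors import InvalidAlphabetError, InvalidPeriodError, NonPrimitiveMotifError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MIN_PERIOD = 2
MAX_PERIOD = 6


@dataclass(frozen=True, order=True)
class MotifClass:
    """Representative of a repeat-unit equivalence class.

    ``canonical`` is the lexicographic minimum over all rotations of the unit
    and all rotations of its reverse complement; it is always primitive, and
    ``period`` equals its length.
    """

    canonical: str
    period: int

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(unit: str) -> None:
    if not unit or any(c not in "ACGT" for c in unit):
        raise InvalidAlphabetError(f"repeat unit {unit!r} contains non-ACGT characters")


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a whole-number repetition of a shorter string.

    A homopolymer (AAAA) or doubled unit (ACAC) is non-primitive; its tandem
    array is identical to that of the shorter unit, so only the shortest
    period describes a repeat tract unambiguously.
    """
    _check_alphabet(unit)
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def _rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def orbit(unit: str) -> frozenset[str]:
    """All strings equivalent to ``unit``: rotations plus rotations of its
    reverse complement."""
    return frozenset(_rotations(unit) + _rotations(reverse_complement(unit)))


@lru_cache(maxsize=None)
def canonical_motif(unit: str) -> MotifClass:
    """Normalise a repeat unit to its motif class.

    Raises
    ------
    InvalidAlphabetError
        if ``unit`` contains characters outside A/C/G/T.
    InvalidPeriodError
        if the unit length is outside [2, 6].
    NonPrimitiveMotifError
        if ``unit`` is a repetition of a shorter unit (its period is
        mis-specified; the shorter unit should be used instead).
    """
    _check_alphabet(unit)
    if not MIN_PERIOD <= len(unit) <= MAX_PERIOD:
        raise InvalidPeriodError(
            f"repeat unit {unit!r} has period {len(unit)}, outside [{MIN_PERIOD}, {MAX_PERIOD}]"
        )
    if not is_primitive(unit):
        raise NonPrimitiveMotifError(f"repeat unit {unit!r} is not primitive")
    rep = min(orbit(unit))
    return MotifClass(canonical=rep, period=len(rep))


@lru_cache(maxsize=None)
def enumerate_motif_classes(period: int) -> tuple[MotifClass, ...]:
    """All primitive motif classes of exactly ``period``, in lexicographic
    order of their canonical representative.

    Class counts for periods 2..6 are 4, 10, 33, 102 and 350.
    """
    if not MIN_PERIOD <= period <= MAX_PERIOD:
        raise InvalidPeriodError(f"period {period} outside [{MIN_PERIOD}, {MAX_PERIOD}]")
    seen: set[str] = set()
    for letters in itertools.product("ACGT", repeat=period):
        unit = "".join(letters)
        if not is_primitive(unit):
            continue
        seen.add(min(orbit(unit)))
    return tuple(MotifClass(c, period) for c in sorted(seen))
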