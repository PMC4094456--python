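"""IUPAC residue alphabets and the alignment-letter extension.

Four validation modes are supported, each tied to one fixed alphabet:

``UNIVERSAL``
    Union of the nucleotide and amino-acid alphabets; accepts any
    (multi)FASTA file built from IUPAC letters.
``DNA``
    The 4 DNA bases plus the 11 IUPAC ambiguity codes. ``U`` is excluded,
    so RNA sequences do not pass.
``RNA``
    Same as DNA with ``U`` replacing ``T``.
``PROTEIN``
    The 20 canonical amino acids plus the IUPAC ambiguity/unknown codes
    ``B``, ``Z``, ``X`` and the later extensions ``J`` (Leu/Ile),
    ``U`` (selenocysteine) and ``O`` (pyrrolysine).

Every mode is additionally extended by the four alignment letters —
space, dash, dot and asterisk — so aligned sequence sets (gapped
rRNA reference alignments, stop-marked protein alignments) validate
in all modes. Residue matching is case-insensitive everywhere.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "ALIGNMENT_LETTERS",
    "Alphabet",
    "CharClass",
    "Mode",
    "alphabet_for",
    "classify_char",
    "is_valid_char",
]

#: Gap/stop characters legal in sequence lines of every mode.
ALIGNMENT_LETTERS: frozenset[str] = frozenset(" -.*")

_DNA_LETTERS = frozenset("ACGTRYSWKMBDHVN")
_RNA_LETTERS = frozenset("ACGURYSWKMBDHVN")
_PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYBZXJUO")
_UNIVERSAL_LETTERS = _DNA_LETTERS | _RNA_LETTERS | _PROTEIN_LETTERS


class Mode(enum.Enum):
    """The four validation modes."""

    UNIVERSAL = "universal"
    DNA = "dna"
    RNA = "rna"
    PROTEIN = "protein"


class CharClass(enum.Enum):
    """Verdict of a single-character membership test."""

    RESIDUE = "residue"
    ALIGNMENT = "alignment"
    INVALID = "invalid"


@dataclass(frozen=True)
class Alphabet:
    """A named residue letter set plus the alignment-letter extension.

    ``residue_letters`` holds the uppercase canonical forms; membership
    tests fold case, so ``a`` and ``A`` are equivalent.
    """

    name: str
    residue_letters: frozenset[str]
    alignment_letters: frozenset[str] = ALIGNMENT_LETTERS
    case_insensitive: bool = True

    def classify(self, c: str) -> CharClass:
        if len(c) != 1:
            raise ValueError("classify expects a single character")
        if c in self.alignment_letters:
            return CharClass.ALIGNMENT
        if c.upper() in self.residue_letters:
            return CharClass.RESIDUE
        return CharClass.INVALID


_ALPHABETS: dict[Mode, Alphabet] = {
    Mode.UNIVERSAL: Alphabet("universal", _UNIVERSAL_LETTERS),
    Mode.DNA: Alphabet("dna", _DNA_LETTERS),
    Mode.RNA: Alphabet("rna", _RNA_LETTERS),
    Mode.PROTEIN: Alphabet("protein", _PROTEIN_LETTERS),
}


def alphabet_for(mode: Mode) -> Alphabet:
    """Return the fixed :class:`Alphabet` for *mode*.

    Raises :class:`ValueError` for anything that is not one of the four
    :class:`Mode` values.
    """
    try:
        return _ALPHABETS[mode]
    except (KeyError, TypeError):
        raise ValueError(f"unknown mode: {mode!r}") from None


def classify_char(c: str, mode: Mode) -> CharClass:
    """Classify a single character under *mode* (total, case-insensitive)."""
    return alphabet_for(mode).classify(c)


def is_valid_char(c: str, mode: Mode) -> bool:
    """True when *c* is a legal sequence character (residue or alignment)."""
    return classify_char(c, mode) is not CharClass.INVALID


@lru_cache(maxsize=None)
def invalid_char_pattern(mode: Mode) -> re.Pattern[str]:
    """Compiled pattern matching the first character illegal under *mode*.

    Used by the lexer to annotate sequence-line tokens at C speed.
    """
    alpha = alphabet_for(mode)
    allowed = set(alpha.alignment_letters)
    for ch in alpha.residue_letters:
        allowed.add(ch)
        allowed.add(ch.lower())
    return re.compile("[^" + re.escape("".join(sorted(allowed))) + "]")
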