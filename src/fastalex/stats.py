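"""Valid-letter counting and candidate-set alphabet detection.

``count_letters`` is the benchmark statistic for a validating parser:
it tallies every residue character (case-folded to uppercase) across the
sequence lines of a file, with the four alignment letters tallied
separately, and it *includes* full validation — invalid input is an
error, never a partial count.

``detect_alphabet`` answers "what kind of sequences are these?" honestly:
because the amino-acid and DNA letter alphabets overlap (heavily so once
ambiguity codes are included), a single forced answer is not robust, so
the result is the *set* of specific modes under which every sequence
character is legal, plus the position at which each rejected mode first
failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alphabets import Mode, invalid_char_pattern
from .lexer import Source, TokenKind, tokenize
from .validator import (
    FastaValidationError,
    LetterCounts,
    _Grammar,
    validate,
)

__all__ = ["LetterCounts", "AlphabetDetection", "count_letters", "detect_alphabet"]

_SPECIFIC_MODES = (Mode.DNA, Mode.RNA, Mode.PROTEIN)


def count_letters(source: Source, mode: Mode = Mode.UNIVERSAL) -> LetterCounts:
    """Count valid letters in *source*, validating it under *mode*.

    Returns a :class:`LetterCounts` with per-letter residue tallies
    (uppercased keys) and separate alignment-letter tallies. Header and
    comment characters are never counted. The first validity issue
    aborts with :class:`FastaValidationError`.
    """
    report = validate(source, mode, fail_fast=True, count_letters=True)
    if not report.valid:
        raise FastaValidationError(report.issues[0])
    assert report.letter_counts is not None
    return report.letter_counts


@dataclass
class AlphabetDetection:
    """Result of candidate-set alphabet detection.

    ``candidates`` holds every specific mode (DNA, RNA, PROTEIN) whose
    alphabet covers all sequence characters — deliberately a set, never
    a forced single answer. ``first_rejection`` maps each excluded mode
    to the ``(line, column)`` of its first offending character.
    """

    candidates: set[Mode] = field(default_factory=set)
    first_rejection: dict[Mode, tuple[int, int]] = field(default_factory=dict)


def detect_alphabet(source: Source) -> AlphabetDetection:
    """Detect which specific alphabets cover *source*'s sequence data.

    The input must be valid under the universal mode; otherwise the
    first issue is raised as :class:`FastaValidationError`. A mode m is
    in the candidate set exactly when the input would validate under m.
    """
    grammar = _Grammar(Mode.UNIVERSAL)
    patterns = {m: invalid_char_pattern(m) for m in _SPECIFIC_MODES}
    rejection: dict[Mode, tuple[int, int]] = {}

    for tok in tokenize(source, Mode.UNIVERSAL):
        issues, accepted = grammar.feed(tok)
        if issues:
            raise FastaValidationError(issues[0])
        if accepted and tok.kind is TokenKind.SEQLINE:
            for m in _SPECIFIC_MODES:
                if m not in rejection:
                    hit = patterns[m].search(tok.text)
                    if hit:
                        rejection[m] = (tok.line, hit.start() + 1)

    return AlphabetDetection(
        candidates={m for m in _SPECIFIC_MODES if m not in rejection},
        first_rejection=rejection,
    )
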