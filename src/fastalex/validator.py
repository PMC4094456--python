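"""Grammar stage: token-order validation, reports and record events.

A FASTA file is valid when the lexer produces only legal tokens and they
appear in the order of this regular grammar::

    file   := record+ EOF
    record := HEADER COMMENT* SEQLINE+

i.e. the input must begin with a header, comments are legal only
immediately after a header, and every record needs at least one sequence
line. Blank lines are issues by default; ``allow_blank_between_records``
tolerates them between a record's last sequence line and the next header
(or the end of file). A sequence line containing a character illegal for
the mode yields ILLEGAL_CHARACTER at its first bad position.

Error recovery resynchronizes at the next header so one corrupt record
yields one issue, not a cascade. ``fail_fast`` stops at the first issue;
``max_issues`` caps a full scan.

For every accepted token an event fires on the optional
:class:`RecordEventHandler`, so lines can be transformed into caller-
defined structures while the file streams through; :func:`iter_records`
is a convenience materialization built on the same machinery.

Coordinates are 1-based for lines and columns (column 0 means the whole
line); byte offsets, where exposed by the lexer, are 0-based.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .alphabets import ALIGNMENT_LETTERS, Mode, alphabet_for
from .lexer import Source, Token, TokenKind, tokenize

__all__ = [
    "IssueCode",
    "ValidationIssue",
    "LetterCounts",
    "ValidationReport",
    "RecordEventHandler",
    "FastaValidationError",
    "validate",
    "iter_records",
]


class IssueCode(enum.Enum):
    """Closed catalogue of validation error codes.

    NO_HEADER_AT_START
        Sequence or comment content appears before any header.
    EMPTY_SEQUENCE
        A header is followed by another header or EOF with no sequence line.
    ILLEGAL_CHARACTER
        A sequence line contains a character outside the mode's alphabet.
    MISPLACED_COMMENT
        A comment line appears after sequence content instead of
        immediately after a header.
    BLANK_LINE
        A blank line in a position where it is not tolerated.
    EMPTY_FILE
        The input contains no lines at all.
    """

    NO_HEADER_AT_START = "NO_HEADER_AT_START"
    EMPTY_SEQUENCE = "EMPTY_SEQUENCE"
    ILLEGAL_CHARACTER = "ILLEGAL_CHARACTER"
    MISPLACED_COMMENT = "MISPLACED_COMMENT"
    BLANK_LINE = "BLANK_LINE"
    EMPTY_FILE = "EMPTY_FILE"


@dataclass(frozen=True)
class ValidationIssue:
    code: IssueCode
    message: str
    line: int
    column: int = 0  # 1-based; 0 when the whole line is at fault
    offending: str = ""


@dataclass
class LetterCounts:
    """Per-letter tallies over accepted sequence lines.

    Residue keys are case-folded to uppercase; the four alignment
    letters are tallied separately so totals with and without gap
    characters are both available.
    """

    residue: dict[str, int] = field(default_factory=dict)
    alignment: dict[str, int] = field(default_factory=dict)

    @property
    def total_residues(self) -> int:
        return sum(self.residue.values())

    @property
    def total_alignment(self) -> int:
        return sum(self.alignment.values())

    def add_line(self, text: str) -> None:
        res, aln = self.residue, self.alignment
        for ch, n in Counter(text).items():
            if ch in ALIGNMENT_LETTERS:
                aln[ch] = aln.get(ch, 0) + n
            else:
                up = ch.upper()
                res[up] = res.get(up, 0) + n


@dataclass
class ValidationReport:
    valid: bool
    issues: list[ValidationIssue]
    record_count: int
    line_count: int
    letter_counts: Optional[LetterCounts] = None


class RecordEventHandler:
    """Callback contract fired once per accepted token, in token order.

    Subclass and override any of the four hooks; the defaults do nothing.
    """

    def on_header(self, token: Token) -> None: ...

    def on_comment(self, token: Token) -> None: ...

    def on_sequence_line(self, token: Token) -> None: ...

    def on_eof(self, token: Token) -> None: ...


class FastaValidationError(ValueError):
    """Raised by strict APIs; carries the offending :class:`ValidationIssue`."""

    def __init__(self, issue: ValidationIssue):
        super().__init__(
            f"line {issue.line}"
            + (f", column {issue.column}" if issue.column else "")
            + f": {issue.code.value}: {issue.message}"
        )
        self.issue = issue


# Grammar machine states.
_START, _AFTER_HEADER, _IN_SEQ, _RECOVER = range(4)


class _Grammar:
    """Single-pass recognizer of ``record := HEADER COMMENT* SEQLINE+``.

    ``feed`` returns ``(issues, accepted)`` for one token: zero or more
    issues (deferred blank-line issues are attributed to their own
    lines and precede any issue on the current token) and whether the
    current token was accepted into the grammar.
    """

    def __init__(self, mode: Mode, allow_blank_between_records: bool = False):
        alphabet_for(mode)  # validate mode eagerly
        self.mode = mode
        self.allow_blank = allow_blank_between_records
        self.state = _START
        self.record_count = 0
        self.saw_content = False
        self._pending_blanks: list[Token] = []

    def _blank_issue(self, tok: Token) -> ValidationIssue:
        return ValidationIssue(
            IssueCode.BLANK_LINE, "blank line not allowed here", tok.line
        )

    def _flush_blanks_as_issues(self) -> list[ValidationIssue]:
        issues = [self._blank_issue(t) for t in self._pending_blanks]
        self._pending_blanks.clear()
        return issues

    def feed(self, tok: Token) -> tuple[list[ValidationIssue], bool]:
        kind = tok.kind

        if kind is TokenKind.EOF:
            issues: list[ValidationIssue] = []
            self._pending_blanks.clear()  # trailing blanks tolerated
            if not self.saw_content:
                issues.append(
                    ValidationIssue(IssueCode.EMPTY_FILE, "input is empty", tok.line)
                )
            elif self.state == _AFTER_HEADER:
                issues.append(
                    ValidationIssue(
                        IssueCode.EMPTY_SEQUENCE,
                        "header has no sequence lines",
                        tok.line,
                        offending="EOF",
                    )
                )
            return issues, True

        self.saw_content = True

        if kind is TokenKind.BLANK:
            if self.allow_blank and self.state == _IN_SEQ:
                self._pending_blanks.append(tok)
                return [], True
            return [self._blank_issue(tok)], False

        if kind is TokenKind.HEADER:
            issues = []
            self._pending_blanks.clear()  # blanks sat between records: legal
            if self.state == _AFTER_HEADER:
                issues.append(
                    ValidationIssue(
                        IssueCode.EMPTY_SEQUENCE,
                        "header has no sequence lines",
                        tok.line,
                        offending="HEADER",
                    )
                )
            self.state = _AFTER_HEADER
            self.record_count += 1
            return issues, True

        # Blank lines tolerated between records turn out to be inside one:
        # a sequence line or comment follows them.
        deferred = self._flush_blanks_as_issues()

        if kind is TokenKind.COMMENT:
            if self.state == _AFTER_HEADER:
                return deferred, True
            if self.state == _RECOVER:
                return deferred, False
            if self.state == _START:
                self.state = _RECOVER
                return deferred + [
                    ValidationIssue(
                        IssueCode.NO_HEADER_AT_START,
                        "comment before the first header",
                        tok.line,
                        offending=";",
                    )
                ], False
            return deferred + [
                ValidationIssue(
                    IssueCode.MISPLACED_COMMENT,
                    "comment is only legal immediately after a header",
                    tok.line,
                    offending=";",
                )
            ], False

        # SEQLINE
        if self.state == _RECOVER:
            return deferred, False
        if self.state == _START:
            self.state = _RECOVER
            return deferred + [
                ValidationIssue(
                    IssueCode.NO_HEADER_AT_START,
                    "sequence data before the first header",
                    tok.line,
                )
            ], False
        if tok.first_invalid is not None:
            self.state = _RECOVER
            bad = tok.text[tok.first_invalid - 1]
            return deferred + [
                ValidationIssue(
                    IssueCode.ILLEGAL_CHARACTER,
                    f"character {bad!r} is not allowed in {self.mode.value} mode",
                    tok.line,
                    tok.first_invalid,
                    bad,
                )
            ], False
        self.state = _IN_SEQ
        return deferred, True


def validate(
    source: Source,
    mode: Mode = Mode.UNIVERSAL,
    *,
    fail_fast: bool = False,
    max_issues: Optional[int] = None,
    allow_blank_between_records: bool = False,
    count_letters: bool = False,
    handler: Optional[RecordEventHandler] = None,
) -> ValidationReport:
    """Validate *source* under *mode* and return a :class:`ValidationReport`.

    ``valid`` is True iff no issues were found. With ``fail_fast`` the
    scan stops at the first issue; otherwise it resynchronizes at the
    next header and reports up to ``max_issues`` issues (unlimited when
    None). ``count_letters`` tallies residue and alignment characters of
    accepted sequence lines into ``report.letter_counts``.

    Unreadable input raises the underlying :class:`OSError` /
    :class:`UnicodeError`; that is an I/O failure, distinct from an
    invalid-content verdict.
    """
    limit = 1 if fail_fast else max_issues
    grammar = _Grammar(mode, allow_blank_between_records)
    issues: list[ValidationIssue] = []
    counts = LetterCounts() if count_letters else None
    line_count = 0

    for tok in tokenize(source, mode):
        new_issues, accepted = grammar.feed(tok)
        if tok.kind is not TokenKind.EOF:
            line_count += 1
        if new_issues:
            issues.extend(new_issues)
            if limit is not None and len(issues) >= limit:
                del issues[limit:]
                break
        if accepted and handler is not None:
            if tok.kind is TokenKind.HEADER:
                handler.on_header(tok)
            elif tok.kind is TokenKind.COMMENT:
                handler.on_comment(tok)
            elif tok.kind is TokenKind.SEQLINE:
                handler.on_sequence_line(tok)
            elif tok.kind is TokenKind.EOF:
                handler.on_eof(tok)
        if accepted and counts is not None and tok.kind is TokenKind.SEQLINE:
            counts.add_line(tok.text)

    return ValidationReport(
        valid=not issues,
        issues=issues,
        record_count=grammar.record_count,
        line_count=line_count,
        letter_counts=counts,
    )


def iter_records(
    source: Source, mode: Mode = Mode.UNIVERSAL
) -> Iterator[tuple[str, list[str], str]]:
    """Stream ``(header_text, comment_texts, sequence)`` tuples, strictly.

    ``header_text`` is the header line without the leading ``>``;
    comments are returned without the leading ``;``. Sequence lines are
    concatenated verbatim, alignment letters included. The first
    validity issue raises :class:`FastaValidationError`.
    """
    grammar = _Grammar(mode)
    header: Optional[str] = None
    comments: list[str] = []
    seq_parts: list[str] = []

    for tok in tokenize(source, mode):
        issues, accepted = grammar.feed(tok)
        if issues:
            raise FastaValidationError(issues[0])
        if not accepted:
            continue
        if tok.kind is TokenKind.HEADER:
            if header is not None:
                yield header, comments, "".join(seq_parts)
            header = tok.text[1:]
            comments, seq_parts = [], []
        elif tok.kind is TokenKind.COMMENT:
            comments.append(tok.text[1:])
        elif tok.kind is TokenKind.SEQLINE:
            seq_parts.append(tok.text)
        elif tok.kind is TokenKind.EOF and header is not None:
            yield header, comments, "".join(seq_parts)
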