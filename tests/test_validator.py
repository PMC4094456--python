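"""Grammar-stage behavior: verdicts, issues, recovery, events, records."""

import io
import itertools
import re

import pytest
from Bio.SeqIO.FastaIO import SimpleFastaParser
from hypothesis import given
from hypothesis import strategies as st

from fastalex.alphabets import Mode
from fastalex.fixtures import (
    CorruptionRecipe,
    FixtureSpec,
    corrupt,
    generate_valid,
)
from fastalex.lexer import Token, TokenKind
from fastalex.validator import (
    FastaValidationError,
    IssueCode,
    RecordEventHandler,
    iter_records,
    validate,
)

I = IssueCode


@pytest.mark.parametrize(
    "text,mode,expected_first",
    [
        (">a\n>b\nAC\n", Mode.DNA, (I.EMPTY_SEQUENCE, 2, 0)),
        ("ACGT\n", Mode.DNA, (I.NO_HEADER_AT_START, 1, 0)),
        (">a\nACGU\n", Mode.DNA, (I.ILLEGAL_CHARACTER, 2, 4)),
        (">a\nAC\n;late\nGT\n", Mode.DNA, (I.MISPLACED_COMMENT, 3, 0)),
        (">a\nAC\n\nGT\n", Mode.DNA, (I.BLANK_LINE, 3, 0)),
        ("", Mode.DNA, (I.EMPTY_FILE, 1, 0)),
        (">a\n", Mode.DNA, (I.EMPTY_SEQUENCE, 2, 0)),
        (";c\n>a\nAC\n", Mode.DNA, (I.NO_HEADER_AT_START, 1, 0)),
    ],
)
def test_invalid_inputs_report_expected_first_issue(text, mode, expected_first):
    report = validate(text, mode)
    assert not report.valid
    first = report.issues[0]
    assert (first.code, first.line, first.column) == expected_first


@pytest.mark.parametrize(
    "text,mode,records",
    [
        (">a\nACGT\n", Mode.DNA, 1),
        (">a\n;note\nAC..G-*\n", Mode.UNIVERSAL, 1),
        (">a\n;n1\n;n2\nACGT\n", Mode.DNA, 1),
        (">\nACGT\n", Mode.DNA, 1),  # empty header text is legal
        (">a\nACGT", Mode.DNA, 1),  # no trailing newline
        (">a\nAC\nGT\n>b\nTT\n", Mode.DNA, 2),
        (">p\nMKV*\n", Mode.PROTEIN, 1),  # '*' legal via alignment extension
    ],
)
def test_valid_inputs(text, mode, records):
    report = validate(text, mode)
    assert report.valid and not report.issues
    assert report.record_count == records


def test_illegal_character_reports_offending_character():
    issue = validate(">a\nACGU\n", Mode.DNA).issues[0]
    assert issue.offending == "U"
    assert issue.code is I.ILLEGAL_CHARACTER


def test_error_recovery_yields_one_issue_per_corrupt_record():
    text = ">a\nAC!T\nGGGG\n>b\nACGT\n>c\nAC?T\nTT\n"
    report = validate(text, Mode.DNA)
    assert [i.code for i in report.issues] == [I.ILLEGAL_CHARACTER] * 2
    assert [i.line for i in report.issues] == [2, 7]
    assert report.record_count == 3


def test_max_issues_caps_the_scan():
    text = "".join(f">r{i}\nAC!T\n" for i in range(10))
    report = validate(text, Mode.DNA, max_issues=3)
    assert len(report.issues) == 3


def test_fail_fast_agrees_with_full_scan_on_the_first_issue():
    text, _ = generate_valid(FixtureSpec(n_records=4, seed=11))
    for code in (I.ILLEGAL_CHARACTER, I.EMPTY_SEQUENCE, I.BLANK_LINE,
                 I.MISPLACED_COMMENT, I.NO_HEADER_AT_START):
        bad, _ = corrupt(text, CorruptionRecipe(code, seed=7))
        full = validate(bad, Mode.DNA).issues[0]
        fast = validate(bad, Mode.DNA, fail_fast=True).issues
        assert len(fast) == 1
        assert (fast[0].code, fast[0].line, fast[0].column) == (
            full.code, full.line, full.column,
        )


class _Recorder(RecordEventHandler):
    def __init__(self):
        self.calls: list[tuple[str, Token]] = []

    def on_header(self, token):
        self.calls.append(("header", token))

    def on_comment(self, token):
        self.calls.append(("comment", token))

    def on_sequence_line(self, token):
        self.calls.append(("seq", token))

    def on_eof(self, token):
        self.calls.append(("eof", token))


def test_events_fire_once_per_accepted_token_in_order():
    text = ">a\n;c\nAC\nGT\n>b\nTT\n"
    rec = _Recorder()
    report = validate(text, Mode.DNA, handler=rec)
    assert report.valid
    assert [name for name, _ in rec.calls] == [
        "header", "comment", "seq", "seq", "header", "seq", "eof",
    ]
    assert [t.line for _, t in rec.calls] == [1, 2, 3, 4, 5, 6, 7]


def test_rejected_tokens_fire_no_events():
    rec = _Recorder()
    validate(">a\nAC!T\nGGGG\n>b\nAC\n", Mode.DNA, handler=rec)
    # the bad seqline and the recovery-skipped line stay silent
    assert [name for name, _ in rec.calls] == ["header", "header", "seq", "eof"]


class TestBlankLineOption:
    def test_blank_between_records_tolerated_only_with_option(self):
        text = ">a\nAC\n\n>b\nGT\n"
        assert not validate(text, Mode.DNA).valid
        assert validate(text, Mode.DNA, allow_blank_between_records=True).valid

    def test_blank_inside_a_record_is_always_an_issue(self):
        text = ">a\nAC\n\nGT\n"
        report = validate(text, Mode.DNA, allow_blank_between_records=True)
        assert [(i.code, i.line) for i in report.issues] == [(I.BLANK_LINE, 3)]

    def test_blank_before_first_header_is_always_an_issue(self):
        report = validate("\n>a\nAC\n", Mode.DNA, allow_blank_between_records=True)
        assert [i.code for i in report.issues] == [I.BLANK_LINE]

    def test_trailing_blanks_before_eof_tolerated_with_option(self):
        text = ">a\nAC\n\n\n"
        assert validate(text, Mode.DNA, allow_blank_between_records=True).valid
        assert not validate(text, Mode.DNA).valid


# --- grammar oracle -------------------------------------------------------

_REALIZE = {"H": ">h", "C": ";c", "S": "A", "B": ""}


def _realize(kind_string: str) -> str:
    return "".join(_REALIZE[k] + "\n" for k in kind_string)


def _oracle_valid(kind_string: str) -> bool:
    """Brute-force recognizer of file := (HEADER COMMENT* SEQLINE+)+."""
    return re.fullmatch(r"(HC*S+)+", kind_string) is not None


@given(st.text(alphabet="HCSB", max_size=8))
def test_verdict_matches_regular_grammar_recognizer(kinds):
    assert validate(_realize(kinds), Mode.UNIVERSAL).valid == _oracle_valid(kinds)


@given(st.text(alphabet="HCSB", max_size=6))
def test_specific_mode_validity_implies_universal_validity(kinds):
    text = _realize(kinds)
    for mode in (Mode.DNA, Mode.RNA, Mode.PROTEIN):
        if validate(text, mode).valid:
            assert validate(text, Mode.UNIVERSAL).valid


# --- iter_records ---------------------------------------------------------

def test_iter_records_concatenates_sequence_lines():
    assert list(iter_records(">a\nAC\nGT\n")) == [("a", [], "ACGT")]


def test_iter_records_preserves_order_comments_and_gaps():
    text = ">a one\n;note\nAC-.\n>b two\nG*T\n"
    assert list(iter_records(text, Mode.UNIVERSAL)) == [
        ("a one", ["note"], "AC-."),
        ("b two", [], "G*T"),
    ]


def test_iter_records_raises_on_first_issue():
    with pytest.raises(FastaValidationError) as exc:
        list(iter_records(">a\nAC!T\n"))
    issue = exc.value.issue
    assert (issue.code, issue.line, issue.column) == (I.ILLEGAL_CHARACTER, 2, 3)


def test_iter_records_agrees_with_biopython_on_generated_files():
    """Independent oracle: Biopython's FASTA parser on gap-free fixtures."""
    for seed in range(5):
        text, _ = generate_valid(
            FixtureSpec(mode=Mode.PROTEIN, n_records=6, seed=seed)
        )
        ours = [(h, s) for h, _, s in iter_records(text, Mode.PROTEIN)]
        theirs = list(SimpleFastaParser(io.StringIO(text)))
        assert ours == theirs
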