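"""Deterministic FASTA fixture generation and targeted corruption.

The generator produces valid (multi)FASTA text with a known shape —
record count, sequence lengths, wrapping width, line-terminator dialect
(including per-line mixed endings), optional comment lines and a
per-position gap probability emulating aligned reference sets — together
with a manifest of per-record lengths and the exact letter counts the
counting statistic must reproduce. All randomness flows through two
generators seeded from a single integer, so the same spec yields
byte-identical output on every platform.

``corrupt`` takes valid text and a recipe naming a validation error
code, injects exactly one defect, and returns the corrupted text along
with the issue (code, line, column) the validator must report first —
a round-trip contract the test-suite exercises at scale.

Sequence composition is shape, not biology: residues are drawn
uniformly from the 4 (DNA/RNA) or 20 canonical (protein) base letters
with a 5% chance of an ambiguity code.
"""

from __future__ import annotations

import enum
import random
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .alphabets import ALIGNMENT_LETTERS, Mode, alphabet_for
from .lexer import Terminator, TokenKind, tokenize
from .validator import IssueCode, LetterCounts, ValidationIssue

__all__ = [
    "TerminatorStyle",
    "FixtureSpec",
    "CorruptionRecipe",
    "PositionPolicy",
    "UnrealizableCorruptionError",
    "generate_valid",
    "stream_records",
    "corrupt",
]

_AMBIGUITY_FRACTION = 0.05
_GAP_CHARS = "-. *"

_CORE_LETTERS = {
    Mode.DNA: "ACGT",
    Mode.RNA: "ACGU",
    Mode.PROTEIN: "ACDEFGHIKLMNPQRSTVWY",
    Mode.UNIVERSAL: "ACDEFGHIKLMNPQRSTUVWY",
}


class TerminatorStyle(enum.Enum):
    LF = "LF"
    CRLF = "CRLF"
    CR = "CR"
    MIXED = "MIXED"


_STYLE_CHARS = {
    TerminatorStyle.LF: "\n",
    TerminatorStyle.CRLF: "\r\n",
    TerminatorStyle.CR: "\r",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for deterministic generation of a valid FASTA file.

    ``length_min``/``length_max`` bound the total sequence characters
    per record (gaps included when ``gap_prob`` > 0); the manifest
    records the realized residue count of each record. ``gap_prob`` is
    the per-position chance of an alignment character, emulating
    aligned data sets; ``comment_prob`` is the per-record chance of a
    comment line after the header.
    """

    mode: Mode = Mode.DNA
    n_records: int = 10
    length_min: int = 50
    length_max: int = 200
    line_width: int = 70
    terminator: TerminatorStyle = TerminatorStyle.LF
    comment_prob: float = 0.0
    gap_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 1:
            raise ValueError("n_records must be positive")
        if not (1 <= self.length_min <= self.length_max):
            raise ValueError("need 1 <= length_min <= length_max")
        if self.line_width < 1:
            raise ValueError("line_width must be positive")
        for p in (self.comment_prob, self.gap_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _letter_pool(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    core = _CORE_LETTERS[spec.mode]
    ambiguity = sorted(set(alphabet_for(spec.mode).residue_letters) - set(core))
    pool = list(core) + ambiguity
    weights = [(1.0 - _AMBIGUITY_FRACTION) / len(core)] * len(core) + [
        _AMBIGUITY_FRACTION / len(ambiguity)
    ] * len(ambiguity)
    if spec.gap_prob > 0:
        pool += list(_GAP_CHARS)
        weights = [w * (1.0 - spec.gap_prob) for w in weights] + [
            spec.gap_prob / len(_GAP_CHARS)
        ] * len(_GAP_CHARS)
    letters = np.frombuffer("".join(pool).encode("ascii"), dtype="S1")
    probs = np.asarray(weights)
    return letters, probs / probs.sum()


def _record_texts(
    spec: FixtureSpec,
    counts: Optional[LetterCounts] = None,
    records_meta: Optional[list[dict]] = None,
) -> Iterator[str]:
    """Yield one string per record; ``''.join`` of them is the fixture."""
    rng = random.Random(spec.seed)
    np_rng = np.random.default_rng(spec.seed)
    letters, probs = _letter_pool(spec)
    fixed_term = _STYLE_CHARS.get(spec.terminator)
    term_choices = list(_STYLE_CHARS.values())

    def term() -> str:
        return fixed_term if fixed_term is not None else rng.choice(term_choices)

    for i in range(spec.n_records):
        length = rng.randint(spec.length_min, spec.length_max)
        drawn = letters[np_rng.choice(len(letters), size=length, p=probs)]
        seq = drawn.tobytes().decode("ascii")
        lines = [
            seq[j : j + spec.line_width] for j in range(0, length, spec.line_width)
        ]
        # A wholly-whitespace slice would lex as a blank line, not a
        # sequence line; pin its first position to a core residue.
        for k, ln in enumerate(lines):
            if ln.isspace():
                lines[k] = _CORE_LETTERS[spec.mode][0] + ln[1:]

        parts = [f">rec{i} synthetic fixture{term()}"]
        if spec.comment_prob > 0 and rng.random() < spec.comment_prob:
            parts.append(f"; fixture comment for rec{i}{term()}")
        for ln in lines:
            parts.append(ln + term())

        if counts is not None:
            for ln in lines:
                counts.add_line(ln)
        if records_meta is not None:
            n_gaps = sum(ln.count(g) for g in ALIGNMENT_LETTERS for ln in lines)
            records_meta.append(
                {"id": f"rec{i}", "length": length, "residues": length - n_gaps}
            )
        yield "".join(parts)


def stream_records(spec: FixtureSpec) -> Iterator[str]:
    """Stream the fixture record-by-record without materializing it."""
    return _record_texts(spec)


def generate_valid(spec: FixtureSpec) -> tuple[str, dict]:
    """Generate a valid FASTA fixture and its manifest.

    Returns ``(text, manifest)`` where the manifest carries the spec
    echo, per-record lengths/residue counts and the exact letter counts
    that :func:`fastalex.stats.count_letters` must report for the text.
    Deterministic: the same spec (same seed) is byte-identical.
    """
    counts = LetterCounts()
    records_meta: list[dict] = []
    text = "".join(_record_texts(spec, counts, records_meta))
    manifest = {
        "mode": spec.mode.value,
        "n_records": spec.n_records,
        "seed": spec.seed,
        "records": records_meta,
        "letter_counts": {
            "residue": dict(sorted(counts.residue.items())),
            "alignment": dict(sorted(counts.alignment.items())),
            "total_residues": counts.total_residues,
            "total_alignment": counts.total_alignment,
        },
    }
    return text, manifest


class PositionPolicy(enum.Enum):
    RANDOM_RECORD = "random-record"
    FIXED_LINE = "fixed-line"


@dataclass(frozen=True)
class CorruptionRecipe:
    """One targeted defect to inject into valid FASTA text.

    ``line`` is consulted only under the fixed-line policy and must then
    name a 1-based line of the kind the corruption operates on.
    """

    target_issue: IssueCode
    policy: PositionPolicy = PositionPolicy.RANDOM_RECORD
    seed: int = 0
    line: Optional[int] = None


class UnrealizableCorruptionError(ValueError):
    """The recipe cannot be realized on the given text."""


def _pick(
    recipe: CorruptionRecipe, rng: random.Random, candidates: list[int]
) -> int:
    """Choose the index (into the line list) the corruption targets."""
    if not candidates:
        raise UnrealizableCorruptionError(
            f"no line suitable for {recipe.target_issue.value} in this text"
        )
    if recipe.policy is PositionPolicy.FIXED_LINE:
        if recipe.line is None:
            raise UnrealizableCorruptionError("fixed-line policy needs a line")
        if (recipe.line - 1) not in candidates:
            raise UnrealizableCorruptionError(
                f"line {recipe.line} is not a valid target for "
                f"{recipe.target_issue.value}"
            )
        return recipe.line - 1
    return rng.choice(candidates)


def corrupt(
    valid_text: str, recipe: CorruptionRecipe
) -> tuple[str, ValidationIssue]:
    """Inject the recipe's defect and return (corrupted text, expected issue).

    The returned issue gives the code, line and column the validator
    must report *first* when run on the corrupted text (any mode for
    structural defects; ILLEGAL_CHARACTER injects ``!``, illegal in
    every mode). Raises :class:`UnrealizableCorruptionError` when the
    text offers no site for the requested defect.
    """
    rng = random.Random(recipe.seed)
    lines: list[tuple[TokenKind, str, str]] = [
        (t.kind, t.text, t.terminator.value)
        for t in tokenize(valid_text)
        if t.kind is not TokenKind.EOF
    ]
    code = recipe.target_issue

    def kind_indices(kind: TokenKind) -> list[int]:
        return [i for i, (k, _, _) in enumerate(lines) if k is kind]

    def ensure_terminated(i: int) -> None:
        if lines[i][2] == "":
            lines[i] = (lines[i][0], lines[i][1], "\n")

    if code is IssueCode.EMPTY_FILE:
        return "", ValidationIssue(code, "input is empty", 1)

    if code is IssueCode.NO_HEADER_AT_START:
        headers = kind_indices(TokenKind.HEADER)
        if not headers or headers[0] != 0:
            raise UnrealizableCorruptionError("text does not start with a header")
        del lines[0]
        expected = ValidationIssue(code, "first header removed", 1)

    elif code is IssueCode.EMPTY_SEQUENCE:
        i = _pick(recipe, rng, kind_indices(TokenKind.HEADER))
        lines.insert(i + 1, lines[i])
        expected = ValidationIssue(
            code, "duplicated header", i + 2, offending="HEADER"
        )

    elif code is IssueCode.ILLEGAL_CHARACTER:
        i = _pick(recipe, rng, kind_indices(TokenKind.SEQLINE))
        kind, text, term = lines[i]
        col = rng.randrange(len(text)) + 1
        lines[i] = (kind, text[: col - 1] + "!" + text[col:], term)
        expected = ValidationIssue(code, "injected '!'", i + 1, col, "!")

    elif code is IssueCode.MISPLACED_COMMENT:
        i = _pick(recipe, rng, kind_indices(TokenKind.SEQLINE))
        ensure_terminated(i)
        lines.insert(i + 1, (TokenKind.COMMENT, "; injected comment", lines[i][2]))
        expected = ValidationIssue(code, "comment after sequence", i + 2, offending=";")

    elif code is IssueCode.BLANK_LINE:
        # The blank inherits the target's terminator: a CR-terminated line
        # followed by "" + LF would fuse into one CRLF and no blank at all.
        i = _pick(recipe, rng, kind_indices(TokenKind.SEQLINE))
        ensure_terminated(i)
        lines.insert(i + 1, (TokenKind.BLANK, "", lines[i][2]))
        expected = ValidationIssue(code, "injected blank line", i + 2)

    else:
        raise UnrealizableCorruptionError(f"unsupported issue code: {code!r}")

    return "".join(text + term for _, text, term in lines), expected
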