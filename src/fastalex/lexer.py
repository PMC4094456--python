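"""Streaming lexical analysis: raw characters -> classified line tokens.

The lexer is the first of the two validation stages. It splits the input
into lines, classifies each line by its first character (``>`` header,
``;`` comment, whitespace-only blank, anything else a sequence line) and
records position metadata. The three line-terminator dialects — LF
(Unix), CRLF (Microsoft), CR (classic Apple) — are all recognised, and
may be mixed freely within one file; each token records the style it was
terminated with, so concatenating ``text + terminator`` over the token
stream reconstructs the input byte-for-byte.

Sequence lines are additionally scanned against the mode's alphabet:
a line containing an illegal character is still emitted as a token, but
carries the 1-based column of the first offending character. Deciding
what to do about that is the grammar stage's job (`fastalex.validator`),
which keeps the lexer a pure tokenizer.

Memory use is bounded by the longest line, never by the stream length:
input is consumed in chunks and only the current partial line is
buffered. Bytes are decoded as Latin-1 (an ASCII-transparent 1:1 byte
mapping), so arbitrary non-ASCII bytes survive in header/comment text
and surface as illegal characters inside sequence lines.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass
from os import PathLike
from typing import IO, Iterable, Iterator, Union

from .alphabets import Mode, invalid_char_pattern

__all__ = ["Terminator", "TokenKind", "Token", "tokenize"]

_DEFAULT_CHUNK = 64 * 1024


class TokenKind(enum.Enum):
    HEADER = "HEADER"
    COMMENT = "COMMENT"
    SEQLINE = "SEQLINE"
    BLANK = "BLANK"
    EOF = "EOF"


class Terminator(enum.Enum):
    """Line-terminator style; ``value`` is the literal character sequence."""

    LF = "\n"
    CRLF = "\r\n"
    CR = "\r"
    NONE = ""


@dataclass(frozen=True)
class Token:
    """One lexed line (or the end-of-file marker).

    ``text`` is the line content without its terminator; ``line`` is
    1-based, ``byte_offset`` is the 0-based offset of the line start.
    ``first_invalid`` is set only on SEQLINE tokens that contain a
    character illegal under the lexing mode: the 1-based column of the
    first such character.
    """

    kind: TokenKind
    text: str
    line: int
    byte_offset: int
    terminator: Terminator
    first_invalid: int | None = None


Source = Union[str, bytes, PathLike, IO, Iterable[Union[str, bytes]]]


def _iter_chunks(source: Source, chunk_size: int) -> Iterator[str]:
    """Normalize the many accepted source shapes to an iterator of str."""
    if isinstance(source, str):
        yield source
        return
    if isinstance(source, bytes):
        yield source.decode("latin-1")
        return
    if isinstance(source, PathLike):
        with open(source, "rb") as fh:
            while chunk := fh.read(chunk_size):
                yield chunk.decode("latin-1")
        return
    if hasattr(source, "read"):
        while chunk := source.read(chunk_size):
            yield chunk.decode("latin-1") if isinstance(chunk, bytes) else chunk
        return
    for piece in source:
        if piece:
            yield piece.decode("latin-1") if isinstance(piece, bytes) else piece


def tokenize(
    source: Source,
    mode: Mode = Mode.UNIVERSAL,
    *,
    chunk_size: int = _DEFAULT_CHUNK,
) -> Iterator[Token]:
    """Lazily tokenize *source* into an ordered stream of :class:`Token`.

    *source* may be in-memory text/bytes, an open text or binary stream,
    a :class:`os.PathLike`, or any iterable of text/byte chunks. The
    token stream always ends with exactly one EOF token whose line
    number is one past the last line. A final line without a terminator
    is a complete token with ``Terminator.NONE``.

    The token sequence (kinds, texts, line numbers) is invariant under
    the chunking of the input and under rewriting terminators between
    the three dialects.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be positive")
    invalid_re = invalid_char_pattern(mode)
    line_no = 1
    offset = 0

    def emit(text: str, term: Terminator) -> Token:
        nonlocal line_no, offset
        if text.startswith(">"):
            kind = TokenKind.HEADER
            first_bad = None
        elif text.startswith(";"):
            kind = TokenKind.COMMENT
            first_bad = None
        elif not text or text.isspace():
            kind = TokenKind.BLANK
            first_bad = None
        else:
            kind = TokenKind.SEQLINE
            m = invalid_re.search(text)
            first_bad = m.start() + 1 if m else None
        tok = Token(kind, text, line_no, offset, term, first_bad)
        line_no += 1
        offset += len(text) + len(term.value)
        return tok

    buf = ""
    for chunk in _iter_chunks(source, chunk_size):
        data = buf + chunk
        # Hold back a trailing CR: it may pair with an LF in the next chunk.
        safe_end = len(data) - 1 if data.endswith("\r") else len(data)
        pos = 0
        while pos < safe_end:
            i_lf = data.find("\n", pos, safe_end)
            i_cr = data.find("\r", pos, safe_end)
            if i_lf == -1 and i_cr == -1:
                break
            if i_cr == -1 or (i_lf != -1 and i_lf < i_cr):
                yield emit(data[pos:i_lf], Terminator.LF)
                pos = i_lf + 1
            elif data[i_cr + 1 : i_cr + 2] == "\n":  # safe: i_cr < safe_end
                yield emit(data[pos:i_cr], Terminator.CRLF)
                pos = i_cr + 2
            else:
                yield emit(data[pos:i_cr], Terminator.CR)
                pos = i_cr + 1
        buf = data[pos:]

    if buf:
        if buf.endswith("\r"):
            yield emit(buf[:-1], Terminator.CR)
        else:
            yield emit(buf, Terminator.NONE)
    yield Token(TokenKind.EOF, "", line_no, offset, Terminator.NONE)
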