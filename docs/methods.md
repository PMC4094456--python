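# Methods

## Two-stage validation

`fastalex` separates FASTA validation into lexical analysis and grammar
checking, the standard decomposition in compiler construction. The
lexer (`fastalex.lexer`) is a single forward scan that partitions the
input into line tokens — HEADER (`>`…), COMMENT (`;`…), BLANK
(empty/whitespace-only), SEQLINE (everything else) — plus one final EOF
token. Tokens carry their text without the terminator, the 1-based line
number, the 0-based byte offset of the line start, and the terminator
style; concatenating `text + terminator` over the stream reconstructs
the input exactly, a property the suite fuzzes. The grammar stage
(`fastalex.validator`) is a four-state machine recognizing

```
file   := record+ EOF
record := HEADER COMMENT* SEQLINE+
```

A file is valid iff the lexer produced only legal tokens and the
machine accepted their order. The machine is deliberately tiny so that
it can be checked exhaustively: the suite enumerates every token-kind
string of length ≤ 5 (1,365 cases) and compares the verdict against a
regular-expression recognizer of the same grammar.

### Division of labor for illegal characters

The lexer annotates a SEQLINE with the first character outside the
mode's alphabet; the validator turns that annotation into an
ILLEGAL_CHARACTER issue and skips ahead. Whether the rejection happens
lexically or grammatically is observationally equivalent; annotating in
the lexer keeps tokenization total (every input tokenizes) and lets the
per-line scan run as one compiled regular-expression search rather than
a per-character Python loop, which is what makes ~100 MB inputs
practical in pure Python.

### Error taxonomy and recovery

Six closed issue codes: NO_HEADER_AT_START, EMPTY_SEQUENCE,
ILLEGAL_CHARACTER, MISPLACED_COMMENT, BLANK_LINE, EMPTY_FILE. Lines and
columns are 1-based (column 0 = whole line); byte offsets 0-based.
After NO_HEADER_AT_START or ILLEGAL_CHARACTER the validator
resynchronizes at the next header, so one corrupt record yields one
issue. A misplaced comment is reported and skipped without abandoning
the record, since the surrounding sequence is intact. `fail_fast` stops
at the first issue and is guaranteed to agree with the full scan on it;
`max_issues` caps a full scan (CLI default 20, `--all-errors` lifts it).

Decisions taken where the format is genuinely underspecified:

* **Comments** are `;`-prefixed (the original FASTA dialect) and legal
  only immediately after a header, multiple allowed.
* **Zero-length records** (header followed by header or EOF) are
  invalid; EMPTY_SEQUENCE is reported at the second header's line, or
  at the EOF line when the file ends early.
* **Empty header text** (`>` alone) is valid: the grammar constrains
  order, not header content.
* **Blank lines** are invalid by default — the strict reading befits a
  validator — but `allow_blank_between_records` tolerates them between
  a record's last sequence line and the next header, and likewise
  before EOF (trailing newline padding is the same files-in-the-wild
  case). Blanks before the first header or inside a record are always
  issues; tolerated blanks that turn out to sit inside a record (a
  sequence line follows them) are reported retroactively at their own
  lines.
* **A comment before the first header** reports NO_HEADER_AT_START:
  the file must open with a header, and the verdict is the same either
  way.

### Line endings and encoding

LF, CRLF and CR are recognized, and may be mixed within one file; each
token records its own style. A final line without a terminator is a
complete token. A CR at a chunk boundary is held back until the next
chunk decides whether it heads a CRLF. Input bytes are decoded as
Latin-1 — an ASCII-transparent, lossless byte↔char mapping — so
arbitrary non-ASCII bytes survive in header/comment text and surface as
illegal characters in sequence lines. Memory is bounded by the longest
line: only the current partial line is buffered.

One non-obvious consequence of mixed endings, found by the fuzz suite:
the byte sequence `\r` `\n` is always *one* CRLF terminator, so an
empty line terminated with LF directly after a CR-terminated line is
indistinguishable from a single CRLF. Harnesses that re-render
terminators per line (and the corruption generator, which inserts blank
lines) must therefore never produce that combination when a blank line
is intended; `corrupt()` makes inserted lines inherit the terminator of
the line they follow.

## Alphabets

The IUPAC one-letter codes, uppercase canonical, matched
case-insensitively: nucleotide = 4 bases + 11 ambiguity codes
(DNA `ACGT`+`RYSWKMBDHVN`; RNA with `U` for `T`); protein = 20
canonical + `B Z X` (ambiguity/unknown) + `J U O` (later IUPAC
extensions — included so SWISSPROT-style data passes); universal =
union of the three. DNA excludes `U` and RNA excludes `T`, the only
reading under which those modes validate *only* their sequence type.
All four modes share the alignment-letter extension {space, `-`, `.`,
`*`}; `*` is an alignment letter in every mode, not a protein-only stop
character. Residue and alignment sets are disjoint by construction and
checked per byte value against an independently hand-written table in
the tests.

## Letter counting and alphabet detection

`count_letters` is the canonical benchmark statistic for a validating
parser: tally every residue character across sequence lines, case-folded
to uppercase. Counting *includes* validation; invalid input raises
rather than returning a partial count. Alignment characters are
excluded from the residue total but tallied separately, so analyses that
do or do not count gaps as "valid letters" are both computable.

`detect_alphabet` returns every specific mode (DNA, RNA, PROTEIN) whose
alphabet covers all sequence characters, plus the first offending
(line, column) per rejected mode. It never forces a single answer:
with ambiguity codes included the DNA alphabet is a subset of the
protein alphabet, so any tie-break would be a heuristic, not a
detection. The invariant `m ∈ candidates ⇔ validate(x, m).valid` is
fuzz-checked.

## Synthetic fixtures

The generator (`fastalex.fixtures`) replaces external evaluation data
with deterministic synthetic files whose expected properties are known
exactly. It emulates the *shapes* that matter to a format validator —
record count, sequence length range, wrapping width, terminator dialect
(including per-line mixed endings), optional `;` comment lines, and a
per-position gap probability emulating aligned reference sets (gapped
rRNA alignments being the archetype). It does not emulate biological
composition: residues are uniform over the 4 (DNA/RNA) or 20 canonical
(protein) base letters with a 5% ambiguity-code chance, a shape-only
default. Passing tests therefore demonstrate format-level correctness
on realistic file *structure*, not performance on realistic sequence
*content* — irrelevant to a validator, which inspects characters, not
composition.

`length_min`/`length_max` bound total sequence characters per record;
the manifest records each record's realized residue count and the exact
letter counts the counting statistic must reproduce. Structural
randomness flows through `random.Random(seed)` and letter draws through
`numpy.random.default_rng(seed)`, so one integer seed makes the output
byte-identical across platforms. A wrapped slice that lands
whitespace-only (possible at high gap probability, since space is a gap
letter) would lex as a blank line; its first position is pinned to a
core residue.

`corrupt()` injects exactly one defect per recipe and returns the issue
(code, line, column) the validator must report first: `!` replacement
for ILLEGAL_CHARACTER (illegal in every mode, keeping recipes
mode-free), header duplication for EMPTY_SEQUENCE, first-header
deletion for NO_HEADER_AT_START, comment/blank insertion after a
sequence line for MISPLACED_COMMENT/BLANK_LINE, full truncation for
EMPTY_FILE. Target sites are chosen by seeded draw (`random-record`) or
pinned (`fixed-line`); an unrealizable recipe raises explicitly.

## Problem sizes and numerical choices

The test suite and acceptance script run: exhaustive grammar
enumeration to length 5 (1,365 strings); 500 fuzzed files × 4
terminator renderings for ending-invariance; 1,000 generated files
across the four modes for count-oracle agreement; 500 generate→corrupt
round trips; 200 files for detection consistency; and one ~107 MB
(120,000 records × 700–1,000 characters) streamed multi-FASTA for the
scale check, which asserts peak traced memory below 64 MiB — in
practice ~0.03 MiB, independent of input size — and reports throughput
without asserting any wall-clock figure, since that is
hardware-dependent. Oracles are written independently of the code paths
they check: a regex recognizer for the grammar, a lexer-free
`splitlines` character scan for the counts, Biopython's FASTA parser
for record materialization.

## Known limitations

* FASTQ, gzip transparency and multi-byte encodings in sequence lines
  are out of scope (wrap externally; decode before feeding).
* Duplicate-ID detection, alignment-length uniformity and wrap-width
  enforcement are lint-style checks, deliberately not validity rules.
* No codon tables, complementation, translation, or user-defined
  alphabets.
* Detection is exact set membership, not probabilistic inference; a
  protein sequence consisting only of `A/C/G/T` letters legitimately
  detects as DNA as well — that honesty is the point.
* Throughput is pure-Python-bound (single-digit MB/s per CPU in the
  acceptance script's own measurement, which includes generation and
  allocation tracing); the design goal here is accuracy, bounded memory
  and a stable contract, not matching compiled parsers.
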