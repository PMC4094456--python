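# fastalex

Streaming validation and parsing of FASTA formatted sequence data, built
the way a compiler front end is built: a **lexer** turns the character
stream into classified line tokens, and a **grammar stage** checks that
the tokens appear in a legal order. A file is valid exactly when it
contains only legal tokens in the right order.

FASTA is the de facto exchange format for biological sequences, yet most
ad-hoc parsers stumble over the classic failure modes: system-specific
line endings (LF / CRLF / CR, often mixed in one file), characters
outside the IUPAC alphabets, gap characters in aligned reference sets,
and semantically broken files (headers without sequences, sequence data
before any header). `fastalex` is for pipeline authors and
bioinformaticians who need a fast, accurate, standardized verdict on
large multi-FASTA inputs — as a Python library with an event-driven
callback API, and as a shell tool whose exit code drives pipelines.

## The model

The lexer classifies each line by its first character and emits one
token per line plus a final EOF token:

| kind    | rule                                   |
|---------|----------------------------------------|
| HEADER  | line starts with `>`                   |
| COMMENT | line starts with `;`                   |
| BLANK   | line is empty or whitespace-only       |
| SEQLINE | anything else                          |

All three line-terminator dialects are recognized, may be mixed freely,
and never change the verdict. The grammar stage then enforces the
regular grammar

```
file   := record+ EOF
record := HEADER COMMENT* SEQLINE+
```

with error recovery at the next header, so one corrupt record produces
one issue rather than a cascade.

Four validation modes define the legal sequence characters, following
the IUPAC one-letter codes:

* **universal** — union of the nucleotide and amino-acid alphabets
* **dna** — `ACGT` + ambiguity codes `RYSWKMBDHVN`
* **rna** — the same with `U` replacing `T`
* **protein** — 20 canonical residues + `BZX` + extensions `JUO`

Every mode is extended by the four **alignment letters** — space, dash
`-`, dot `.`, asterisk `*` — so aligned sequence sets (gapped rRNA
reference alignments, stop-marked protein alignments) validate in every
mode. Matching is case-insensitive.

On top of the validator sit two small statistics: `count_letters`
(per-letter tallies of valid residues, with alignment characters tallied
separately — counting always includes validation) and
`detect_alphabet`, which reports the *set* of specific alphabets
covering the input. Because the amino-acid and DNA alphabets overlap —
every DNA letter, ambiguity codes included, is also a protein letter —
a forced single answer would be a guess, so the API never breaks the tie.

## Worked example

Generate a small gapped DNA fixture, then validate and count it:

```
$ fastalex fixture --mode dna --records 2 --length-min 40 --length-max 60 \
      --gap-prob 0.1 --seed 7 --out demo.fa
wrote demo.fa (144 bytes)

$ fastalex validate --mode dna --counts demo.fa ; echo "exit=$?"
A	19
C	20
G	26
K	1
M	2
N	1
R	1
S	1
T	14
Y	1
 	1
*	3
-	2
.	2
exit=0
```

Each TSV row is one letter and its tally across all sequence lines:
of the 94 sequence characters, 79 are the four bases, 7 are ambiguity
codes (`K M N R S Y`), and the last four rows are the 8 alignment
letters (one space, three `*`, two `-`, two `.`), reported separately
from the residue total. Exit code 0 means the file is valid DNA.

Alphabet detection returns the honest candidate set — this fixture is
legal DNA *and* legal protein, since the alphabets overlap:

```
$ fastalex validate --detect demo.fa
demo.fa	detected	dna,protein
```

Invalid content yields exit code 1 and one tab-separated issue line
(`file  line  col  code  message`) on stderr; here `U` is not a DNA
letter:

```
$ printf '>a\nACGU\n' | fastalex validate --mode dna - ; echo "exit=$?"
-	2	4	ILLEGAL_CHARACTER	character 'U' is not allowed in dna mode
exit=1
```

Exit code 2 signals usage or I/O errors; with several inputs the worst
status wins. The same machinery is available in Python:

```python
import fastalex as fx

report = fx.validate(open("demo.fa", "rb"), fx.Mode.DNA)
counts = fx.count_letters(open("demo.fa", "rb"), fx.Mode.DNA)
for header, comments, seq in fx.iter_records(open("demo.fa", "rb")):
    ...
```

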