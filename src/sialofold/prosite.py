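"""PROSITE-syntax motif compiler, scanner and built-in motif library.

The supported grammar is the pattern subset of PROSITE (the part consumed
by the classic ``ps_scan`` tool):

- elements separated by ``-``;
- ``x`` matches any residue (including the mask letter ``X``);
- a specific residue letter matches only itself — it does NOT match a
  masked ``X`` in the sequence (conservative rule);
- ``[ABC]`` matches any residue in the set;
- ``{ABC}`` matches any residue not in the set;
- ``(n)`` and ``(n,m)`` repeat the preceding element;
- ``<`` anchors the match to the N terminus, ``>`` to the C terminus;
- a trailing ``.`` is ignored.

Coordinates in hits are 1-based inclusive.  Matches at different start
positions may overlap; at one start position only the longest match is
reported.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .seqdb import SequenceRecord

__all__ = [
    "PatternError",
    "PatternElement",
    "MotifPattern",
    "MotifHit",
    "MotifLibrary",
    "compile_pattern",
    "scan_sequence",
    "scan_database",
    "builtin_library",
    "disintegrin_library",
    "load_prosite_file",
    "write_prosite_file",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class PatternError(ValueError):
    """Raised when a PROSITE pattern fails to compile."""


@dataclass(frozen=True)
class PatternElement:
    """One compiled position group of a pattern.

    ``residues`` is the set of accepted sequence letters (already expanded:
    wildcards accept all residues plus ``X``; exclusion sets accept the
    complement plus ``X``).  ``min_repeat``/``max_repeat`` bound how many
    consecutive sequence positions the element consumes.
    """

    residues: frozenset[str]
    min_repeat: int = 1
    max_repeat: int = 1

    def accepts(self, letter: str) -> bool:
        return letter in self.residues


@dataclass(frozen=True)
class MotifPattern:
    pattern_id: str
    prosite_text: str
    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; ``start``/``end`` are 1-based inclusive."""

    pattern_id: str
    record_id: str
    start: int
    end: int
    matched: str


@dataclass
class MotifLibrary:
    """A named, ordered collection of compiled patterns."""

    patterns: dict[str, MotifPattern] = field(default_factory=dict)

    def add(self, pattern: MotifPattern) -> None:
        self.patterns[pattern.pattern_id] = pattern

    def __iter__(self):
        return iter(self.patterns.values())

    def __len__(self) -> int:
        return len(self.patterns)

    def __contains__(self, pattern_id: str) -> bool:
        return pattern_id in self.patterns

    def __getitem__(self, pattern_id: str) -> MotifPattern:
        return self.patterns[pattern_id]


def _parse_repeat(token: str, pos: int) -> tuple[int, int, str]:
    """Parse a leading '(n)' or '(n,m)' off ``token``; return (lo, hi, rest)."""
    close = token.find(")")
    if close < 0:
        raise PatternError(f"unbalanced '(' at element {pos}")
    inner = token[1:close]
    parts = inner.split(",")
    try:
        if len(parts) == 1:
            lo = hi = int(parts[0])
        elif len(parts) == 2:
            lo, hi = int(parts[0]), int(parts[1])
        else:
            raise ValueError
    except ValueError:
        raise PatternError(f"malformed repeat {token[: close + 1]!r} at element {pos}") from None
    if lo < 0 or hi < lo or hi == 0:
        raise PatternError(f"invalid repeat bounds ({lo},{hi}) at element {pos}")
    return lo, hi, token[close + 1 :]


def compile_pattern(prosite_text: str, pattern_id: str = "") -> MotifPattern:
    """Compile PROSITE pattern text into a :class:`MotifPattern`.

    Raises :class:`PatternError` naming the offending element on malformed
    input (unbalanced brackets, zero repeats, unknown residue letters).
    """
    text = prosite_text.strip()
    if text.endswith("."):
        text = text[:-1]
    if not text:
        raise PatternError("empty pattern")

    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    text = text.strip("-")

    elements: list[PatternElement] = []
    for pos, token in enumerate(text.split("-"), start=1):
        token = token.strip()
        if not token:
            raise PatternError(f"empty element at position {pos}")
        if token[0] == "[":
            close = token.find("]")
            if close < 0:
                raise PatternError(f"unbalanced '[' at element {pos}")
            letters = token[1:close].upper()
            bad = set(letters) - _AA_SET
            if bad or not letters:
                raise PatternError(f"invalid residue set {token!r} at element {pos}")
            residues = frozenset(letters)
            rest = token[close + 1 :]
        elif token[0] == "{":
            close = token.find("}")
            if close < 0:
                raise PatternError(f"unbalanced '{{' at element {pos}")
            letters = token[1:close].upper()
            bad = set(letters) - _AA_SET
            if bad or not letters:
                raise PatternError(f"invalid exclusion set {token!r} at element {pos}")
            residues = frozenset(_AA_SET - set(letters)) | {"X"}
            rest = token[close + 1 :]
        elif token[0] in ("x", "X"):
            residues = _AA_SET | {"X"}
            rest = token[1:]
        else:
            letter = token[0].upper()
            if letter not in _AA_SET:
                raise PatternError(f"unknown residue letter {token[0]!r} at element {pos}")
            residues = frozenset({letter})
            rest = token[1:]

        lo, hi = 1, 1
        if rest:
            if rest[0] != "(":
                raise PatternError(f"unexpected text {rest!r} at element {pos}")
            lo, hi, rest = _parse_repeat(rest, pos)
            if rest:
                raise PatternError(f"unexpected text {rest!r} at element {pos}")
        elements.append(PatternElement(frozenset(residues), lo, hi))

    return MotifPattern(
        pattern_id=pattern_id or prosite_text.strip().rstrip("."),
        prosite_text=prosite_text.strip(),
        elements=tuple(elements),
        anchored_start=anchored_start,
        anchored_end=anchored_end,
    )


def _longest_match(pattern: MotifPattern, seq: str, start: int) -> int | None:
    """Length of the longest match of ``pattern`` beginning at ``start``."""
    n = len(seq)
    elements = pattern.elements

    def rec(ei: int, si: int) -> int | None:
        if ei == len(elements):
            if pattern.anchored_end and si != n:
                return None
            return si - start
        elem = elements[ei]
        # greedy: try the longest repeat count first
        hi = min(elem.max_repeat, n - si)
        if hi < elem.min_repeat:
            return None
        # verify prefix acceptance incrementally
        ok = 0
        while ok < hi and elem.accepts(seq[si + ok]):
            ok += 1
        for take in range(min(ok, hi), elem.min_repeat - 1, -1):
            result = rec(ei + 1, si + take)
            if result is not None:
                return result
        return None

    return rec(0, start)


def scan_sequence(pattern: MotifPattern, record: SequenceRecord) -> list[MotifHit]:
    """Report every match start (overlaps allowed), longest match per start."""
    seq = record.sequence
    starts = [0] if pattern.anchored_start else range(len(seq))
    hits: list[MotifHit] = []
    for s in starts:
        if s >= len(seq):
            break
        length = _longest_match(pattern, seq, s)
        if length is not None and length > 0:
            hits.append(
                MotifHit(
                    pattern_id=pattern.pattern_id,
                    record_id=record.record_id,
                    start=s + 1,
                    end=s + length,
                    matched=seq[s : s + length],
                )
            )
    return hits


def scan_database(
    library: MotifLibrary | Iterable[MotifPattern],
    records: Sequence[SequenceRecord],
) -> tuple[list[MotifHit], dict[str, bool]]:
    """Scan every record with every pattern.

    Returns the hit list sorted by ``(record_id, start, pattern_id)`` and a
    per-record flag that is true iff the record has at least one hit.
    """
    patterns = list(library)
    hits: list[MotifHit] = []
    flags: dict[str, bool] = {}
    for rec in records:
        rec_hits: list[MotifHit] = []
        for pat in patterns:
            rec_hits.extend(scan_sequence(pat, rec))
        flags[rec.record_id] = bool(rec_hits)
        hits.extend(rec_hits)
    hits.sort(key=lambda h: (h.record_id, h.start, h.pattern_id))
    return hits, flags


# ---------------------------------------------------------------------------
# Built-in library
# ---------------------------------------------------------------------------

#: Histidine zinc-binding motif required for metalloprotease activity.
ZINC_BINDING = "H-E-x(2)-H-x(2)-G-x(2)-H"
#: Heme-pocket motif of the P450 fold (conserved cysteine ligates the iron).
P450_HEME = "F-x-x-G-x-[HR]-x-C-x-G"
#: P450 active-site motif with the catalytic threonine.
P450_CATALYTIC = "[AG]-G-x-[ED]-T"

#: Integrin-binding triads screened by the disintegrin search.
DISINTEGRIN_TRIADS = ("RGD", "KGD", "KTS", "RTS", "RED")


def builtin_library() -> MotifLibrary:
    """Library with the zinc-binding and P450 motifs."""
    lib = MotifLibrary()
    lib.add(compile_pattern(ZINC_BINDING, "ZINC_BINDING"))
    lib.add(compile_pattern(P450_HEME, "P450_HEME"))
    lib.add(compile_pattern(P450_CATALYTIC, "P450_CATALYTIC"))
    return lib


def disintegrin_library(flank_window: int | None = None) -> MotifLibrary:
    """Library of integrin-binding triad patterns.

    With ``flank_window`` set, each triad is additionally constrained by a
    cysteine within that many residues on each side (the bridge that
    stabilises the presenting hairpin); without it, bare triads are used.
    """
    lib = MotifLibrary()
    for triad in DISINTEGRIN_TRIADS:
        core = "-".join(triad)
        if flank_window is None:
            text = core
        else:
            w = flank_window - 1
            text = f"C-x(0,{w})-{core}-x(0,{w})-C"
        lib.add(compile_pattern(text, f"DISINTEGRIN_{triad}"))
    return lib


def load_prosite_file(path: str | os.PathLike) -> MotifLibrary:
    """Load a PROSITE-format file (ID / PA line subset)."""
    lib = MotifLibrary()
    current_id: str | None = None
    pa_chunks: list[str] = []

    def flush() -> None:
        nonlocal current_id, pa_chunks
        if current_id is not None and pa_chunks:
            lib.add(compile_pattern("".join(pa_chunks), current_id))
        current_id, pa_chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith("ID"):
                flush()
                current_id = line[2:].strip().split(";")[0].strip()
            elif line.startswith("PA"):
                pa_chunks.append(line[2:].strip())
            elif line.startswith("//"):
                flush()
    flush()
    if len(lib) == 0:
        raise PatternError(f"{path}: no patterns found")
    return lib


def write_prosite_file(library: MotifLibrary, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pat in library:
            fh.write(f"ID   {pat.pattern_id}; PATTERN.\n")
            text = pat.prosite_text
            if not text.endswith("."):
                text += "."
            fh.write(f"PA   {text}\n//\n")


def default_disintegrin_file() -> Path:
    """Path of the shipped default disintegrin block file."""
    return Path(__file__).parent / "data" / "disintegrin_blocks.prosite"
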