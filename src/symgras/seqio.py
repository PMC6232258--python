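"""Sequence and alignment I/O plus mechanical curation steps.

Covers reading/writing FASTA, reading aligned FASTA / Stockholm, removal of
identical sequences (with bookkeeping so copy numbers can be restored later)
and cropping an alignment to a domain window such as the GRAS domain.

Conventions
-----------
* All column/position indices are 1-based and inclusive, matching how
  domain boundaries are annotated in practice.
* Sequence ids start with a five-letter species code (e.g. ``MARPO`` for
  *Marchantia polymorpha*); the remainder of the id is the local identifier.
* Nonstandard residue letters: ``X`` is kept (scored as background),
  ``B``/``Z``/``U`` are mapped to ``D``/``E``/``C`` with a warning, a
  terminal ``*`` is stripped, an internal ``*`` is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from symgras.errors import ArgumentError, FormatError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, in the fixed alphabet order used throughout.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Letters accepted inside :class:`ProteinSequence` residues.
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"

_AMBIGUITY_MAP = {"B": "D", "Z": "E", "U": "C"}


def sanitize_residues(raw: str, seq_id: str = "?") -> str:
    """Normalize a raw residue string to the package's residue policy.

    Uppercases, strips one terminal ``*``, maps B/Z/U to D/E/C (warning),
    keeps ``X``. Raises :class:`FormatError` for an internal ``*`` or any
    other letter.
    """
    s = raw.upper()
    if s.endswith("*"):
        s = s[:-1]
    if "*" in s:
        raise FormatError(f"internal stop codon '*' in sequence {seq_id!r}")
    if not s:
        raise FormatError(f"empty residue string for sequence {seq_id!r}")
    mapped = []
    warned = set()
    for ch in s:
        if ch in VALID_RESIDUES:
            mapped.append(ch)
        elif ch in _AMBIGUITY_MAP:
            if ch not in warned:
                logger.warning(
                    "sequence %s: mapping ambiguous residue %s -> %s",
                    seq_id, ch, _AMBIGUITY_MAP[ch],
                )
                warned.add(ch)
            mapped.append(_AMBIGUITY_MAP[ch])
        else:
            raise FormatError(
                f"invalid residue letter {ch!r} in sequence {seq_id!r}"
            )
    return "".join(mapped)


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with a species-coded identifier.

    ``source_tag`` records whether the sequence came from a genome, a
    transcriptome or the synthetic generator; transcriptome evidence is
    treated as soft when absences are interpreted downstream.
    """

    id: str
    residues: str
    source_tag: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains invalid letters {sorted(bad)};"
                " pass the raw string through sanitize_residues() first"
            )

    @property
    def species_code(self) -> str:
        """Five-letter species code parsed from the id prefix."""
        return parse_species_code(self.id)

    @property
    def local_id(self) -> str:
        code = self.species_code
        rest = self.id[len(code):].lstrip("_")
        return rest or self.id

    def __len__(self) -> int:
        return len(self.residues)


def parse_species_code(seq_id: str) -> str:
    """Parse the five-letter species code prefix of a sequence id."""
    prefix = seq_id[:5]
    if len(prefix) == 5 and prefix.isalpha():
        return prefix.upper()
    raise ArgumentError(
        f"id {seq_id!r} does not start with a five-letter species code"
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, source_tag: str | None = None) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    The header token before the first whitespace becomes the id. Order is
    preserved. Malformed input (data before the first header, a header with
    no sequence, duplicate ids) raises :class:`FormatError` naming the line.
    An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_line = 0
    chunks: list[str] = []

    def flush() -> None:
        nonlocal cur_id, chunks
        if cur_id is None:
            return
        if not chunks:
            raise FormatError(
                f"{path}: empty record {cur_id!r} at line {cur_line}"
            )
        residues = sanitize_residues("".join(chunks), cur_id)
        records.append(ProteinSequence(cur_id, residues, source_tag))
        cur_id, chunks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: empty header at line {lineno}")
                cur_id = header.split()[0]
                cur_line = lineno
                if cur_id in seen:
                    raise FormatError(
                        f"{path}: duplicate id {cur_id!r} at line {lineno}"
                    )
                seen.add(cur_id)
            else:
                if cur_id is None:
                    raise FormatError(
                        f"{path}: sequence data before first header at line {lineno}"
                    )
                chunks.append(line)
    flush()
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA, wrapping residue lines at ``width``."""
    path = Path(path)
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultipleAlignment:
    """A gapped multiple alignment with ``-`` as the gap character."""

    rows: tuple[tuple[str, str], ...]
    n_columns: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        ncol = len(self.rows[0][1])
        bad = [rid for rid, r in self.rows if len(r) != ncol]
        if bad:
            raise FormatError(
                f"ragged alignment rows (length != {ncol}): {bad}"
            )
        object.__setattr__(self, "n_columns", ncol)
        ids = [rid for rid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate row ids in alignment: {dupes}")

    @classmethod
    def from_rows(cls, rows: Sequence[tuple[str, str]]) -> "MultipleAlignment":
        norm = []
        for rid, r in rows:
            r = r.upper().replace(".", GAP)
            content = sanitize_residues(r.replace(GAP, ""), rid) if r.replace(GAP, "") else ""
            # re-insert gaps around the sanitized content
            out, it = [], iter(content)
            for ch in r:
                out.append(GAP if ch == GAP else next(it))
            norm.append((rid, "".join(out)))
        return cls(tuple(norm))

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r_id, r in self.rows:
            if r_id == rid:
                return r
        raise ArgumentError(f"no alignment row with id {rid!r}")

    def ungapped(self, rid: str) -> ProteinSequence:
        return ProteinSequence(rid, self.row(rid).replace(GAP, ""))

    def column(self, col: int) -> str:
        """1-based column as a string over rows."""
        if not 1 <= col <= self.n_columns:
            raise ArgumentError(f"column {col} outside 1..{self.n_columns}")
        return "".join(r[col - 1] for _, r in self.rows)


def read_alignment(path: str | Path, dialect: str = "auto") -> MultipleAlignment:
    """Read an aligned FASTA or Stockholm file.

    ``dialect`` is ``fasta``, ``stockholm`` or ``auto`` (sniffed from the
    first non-blank line). Stockholm ``.`` gaps are normalized to ``-``.
    Ragged rows raise :class:`FormatError` listing the offending ids.
    """
    path = Path(path)
    if dialect == "auto":
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    dialect = "stockholm" if line.startswith("# STOCKHOLM") else "fasta"
                    break
            else:
                raise FormatError(f"{path}: empty alignment file")
    if dialect == "fasta":
        rows = _read_gapped_fasta(path)
    elif dialect == "stockholm":
        from Bio import AlignIO

        aln = AlignIO.read(str(path), "stockholm")
        rows = [(rec.id, str(rec.seq)) for rec in aln]
    else:
        raise ArgumentError(f"unknown alignment dialect {dialect!r}")
    ncol = len(rows[0][1]) if rows else 0
    bad = [rid for rid, r in rows if len(r) != ncol]
    if bad:
        raise FormatError(
            f"{path}: alignment rows of unequal length (expected {ncol}): {bad}"
        )
    return MultipleAlignment.from_rows(rows)


def _read_gapped_fasta(path: Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    cur_id: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    rows.append((cur_id, "".join(chunks)))
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}: empty header at line {lineno}")
                cur_id, chunks = header.split()[0], []
            else:
                if cur_id is None:
                    raise FormatError(
                        f"{path}: data before first header at line {lineno}"
                    )
                chunks.append(line)
    if cur_id is not None:
        rows.append((cur_id, "".join(chunks)))
    if not rows:
        raise FormatError(f"{path}: no alignment rows found")
    return rows


def write_alignment(msa: MultipleAlignment, path: str | Path, width: int = 60) -> None:
    """Write an alignment as gapped FASTA."""
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def dedupe_identical(
    seqs: Sequence[ProteinSequence],
) -> tuple[list[ProteinSequence], dict[str, list[str]]]:
    """Remove sequences with identical residue strings, keeping the first.

    Returns the kept sequences (input order) and a map from each kept id to
    the ids removed as its duplicates, so that copy-number tabulation can
    restore the removed sequences later.
    """
    kept: list[ProteinSequence] = []
    by_residues: dict[str, str] = {}
    removed: dict[str, list[str]] = {}
    for seq in seqs:
        rep = by_residues.get(seq.residues)
        if rep is None:
            by_residues[seq.residues] = seq.id
            kept.append(seq)
        else:
            removed.setdefault(rep, []).append(seq.id)
    return kept, removed


def crop_alignment(msa: MultipleAlignment, start_col: int, end_col: int) -> MultipleAlignment:
    """Restrict an alignment to a 1-based inclusive column window.

    Used to crop curated alignments down to the GRAS domain. Rows that are
    entirely gaps inside the window are dropped with a warning.
    """
    if not (1 <= start_col <= end_col <= msa.n_columns):
        raise ArgumentError(
            f"window ({start_col},{end_col}) outside 1..{msa.n_columns}"
        )
    rows = []
    for rid, row in msa.rows:
        sub = row[start_col - 1:end_col]
        if set(sub) == {GAP}:
            logger.warning(
                "crop_alignment: dropping row %s (all-gap in columns %d-%d)",
                rid, start_col, end_col,
            )
            continue
        rows.append((rid, sub))
    if not rows:
        raise ArgumentError(
            f"all rows are gap-only in columns {start_col}-{end_col}"
        )
    return MultipleAlignment(tuple(rows))


# ---------------------------------------------------------------------------
# removed_map TSV
# ---------------------------------------------------------------------------

def write_removed_map(removed: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kept_id\tremoved_id\n")
        for kept_id in sorted(removed):
            for rid in removed[kept_id]:
                fh.write(f"{kept_id}\t{rid}\n")


def read_removed_map(path: str | Path) -> dict[str, list[str]]:
    removed: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and header.split("\t")[0] != "kept_id":
            raise FormatError(f"{path}: expected 'kept_id\\tremoved_id' header")
        for line in fh:
            if not line.strip():
                continue
            kept_id, rid = line.rstrip("\n").split("\t")
            removed.setdefault(kept_id, []).append(rid)
    return removed
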