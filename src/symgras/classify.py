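"""Subfamily assignment from model scores and clade-derived cutoffs.

A sequence is assigned to the subfamily whose cutoff it passes; when it
passes several cutoffs the highest bit score wins and a small winning
margin raises the ambiguity flag (the reference procedure resolved such
cases by a joint phylogenetic analysis — this module flags rather than
silently forces a label). A merged ``RAM1+RAD1`` cutoff is resolved to
its better-scoring component unless the component margin is itself below
the ambiguity threshold, in which case the merged label is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from symgras.clade_tools import SUBFAMILIES, CladeCutoff
from symgras.errors import ArgumentError, DataError, FormatError
from symgras.profile_hmm import ScoreRecord
from symgras.seqio import parse_species_code

#: Default ambiguity margin in bits (configurable in all entry points).
DEFAULT_AMBIGUITY_MARGIN = 2.0

UNASSIGNED = "unassigned"


@dataclass
class ScoreTable:
    """Per-sequence, per-model bit scores with at most one record per pair."""

    _scores: dict[tuple[str, str], float] = field(default_factory=dict)
    seq_ids: list[str] = field(default_factory=list)
    model_names: list[str] = field(default_factory=list)

    @classmethod
    def from_records(cls, records: Iterable[ScoreRecord]) -> "ScoreTable":
        table = cls()
        for rec in records:
            table.add(rec)
        return table

    def __post_init__(self) -> None:
        self._seq_set = set(self.seq_ids)
        self._model_set = set(self.model_names)

    def add(self, rec: ScoreRecord) -> None:
        key = (rec.seq_id, rec.model_name)
        if key in self._scores:
            raise DataError(f"duplicate score record for {key}")
        self._scores[key] = rec.bit_score
        if rec.seq_id not in self._seq_set:
            self.seq_ids.append(rec.seq_id)
            self._seq_set.add(rec.seq_id)
        if rec.model_name not in self._model_set:
            self.model_names.append(rec.model_name)
            self._model_set.add(rec.model_name)

    def has(self, seq_id: str, model_name: str) -> bool:
        return (seq_id, model_name) in self._scores

    def get(self, seq_id: str, model_name: str) -> float:
        try:
            return self._scores[(seq_id, model_name)]
        except KeyError:
            raise DataError(f"no score for sequence {seq_id!r} under model {model_name!r}")

    def records(self) -> list[ScoreRecord]:
        return [
            ScoreRecord(s, m, b) for (s, m), b in self._scores.items()
        ]

    def __len__(self) -> int:
        return len(self._scores)

    def to_tsv(self, path: str | Path) -> None:
        from symgras.profile_hmm import write_scores_tsv

        ordered = [
            ScoreRecord(s, m, self._scores[(s, m)])
            for s in self.seq_ids
            for m in self.model_names
            if (s, m) in self._scores
        ]
        write_scores_tsv(ordered, path)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScoreTable":
        from symgras.profile_hmm import read_scores_tsv

        return cls.from_records(read_scores_tsv(path))


@dataclass(frozen=True)
class Assignment:
    """Classification outcome for one sequence."""

    seq_id: str
    species_code: str
    subfamily: str
    best_score_bits: float
    margin_bits: float
    ambiguous_flag: bool

    def __post_init__(self) -> None:
        if self.margin_bits < 0:
            raise ArgumentError("margin_bits must be non-negative")


def classify_sequences(
    scores: ScoreTable,
    cutoffs: Sequence[CladeCutoff],
    ambiguity_margin: float = DEFAULT_AMBIGUITY_MARGIN,
) -> list[Assignment]:
    """Assign each scored sequence to a subfamily or ``unassigned``.

    A sequence's score under a (possibly merged) cutoff is the maximum of
    its component-model scores. Passing no cutoff yields ``unassigned``;
    passing several, the best score wins with ``ambiguous_flag`` set when
    the margin over the runner-up is below ``ambiguity_margin``.
    """
    if not cutoffs:
        raise ArgumentError("no cutoffs supplied")
    for cutoff in cutoffs:
        for comp in cutoff.components:
            if comp not in scores.model_names:
                raise DataError(
                    f"cutoff {cutoff.subfamily!r} references model {comp!r} "
                    "with no scores"
                )
    assignments = []
    for seq_id in scores.seq_ids:
        passing: list[tuple[CladeCutoff, float]] = []
        best_any = -math.inf
        for cutoff in cutoffs:
            s = max(scores.get(seq_id, comp) for comp in cutoff.components)
            best_any = max(best_any, s)
            if s >= cutoff.cutoff_bits:
                passing.append((cutoff, s))
        species = _species_of(seq_id)
        if not passing:
            assignments.append(
                Assignment(seq_id, species, UNASSIGNED, best_any, 0.0, False)
            )
            continue
        passing.sort(key=lambda cs: (-cs[1], cs[0].subfamily))
        cutoff, best = passing[0]
        margin = best - passing[1][1] if len(passing) > 1 else math.inf
        ambiguous = margin < ambiguity_margin
        label = cutoff.subfamily
        if len(cutoff.components) > 1:
            comp_scores = sorted(
                ((scores.get(seq_id, c), c) for c in cutoff.components),
                key=lambda sc: (-sc[0], sc[1]),
            )
            comp_margin = comp_scores[0][0] - comp_scores[1][0]
            if comp_margin < ambiguity_margin:
                ambiguous = True  # keep the merged label
            else:
                label = comp_scores[0][1]
        assignments.append(
            Assignment(seq_id, species, label, best, margin, ambiguous)
        )
    return assignments


def _species_of(seq_id: str) -> str:
    try:
        return parse_species_code(seq_id)
    except ArgumentError:
        return seq_id[:5].upper()


def species_complement(
    assignments: Sequence[Assignment],
    species_code: str,
    removed_map: Mapping[str, Sequence[str]] | None = None,
    subfamilies: Sequence[str] = SUBFAMILIES,
) -> dict[str, int]:
    """Per-subfamily assigned counts for one species.

    Identical sequences collapsed by :func:`symgras.seqio.dedupe_identical`
    are restored through ``removed_map``: each removed id inherits the
    subfamily of its kept representative and is counted under its own
    species code.
    """
    counts_all = tabulate_counts(assignments, removed_map, subfamilies)
    if species_code not in counts_all:
        raise ArgumentError(f"unknown species code {species_code!r}")
    return counts_all[species_code]


def tabulate_counts(
    assignments: Sequence[Assignment],
    removed_map: Mapping[str, Sequence[str]] | None = None,
    subfamilies: Sequence[str] = SUBFAMILIES,
) -> dict[str, dict[str, int]]:
    """Counts per species per subfamily over all assignments."""
    by_id = {a.seq_id: a for a in assignments}
    counts: dict[str, dict[str, int]] = {}

    def ensure(species: str) -> dict[str, int]:
        return counts.setdefault(species, {f: 0 for f in subfamilies})

    for a in assignments:
        row = ensure(a.species_code)
        if a.subfamily != UNASSIGNED:
            row.setdefault(a.subfamily, 0)
            row[a.subfamily] += 1
    for kept_id, removed_ids in (removed_map or {}).items():
        kept = by_id.get(kept_id)
        if kept is None:
            raise DataError(f"removed_map references unknown kept id {kept_id!r}")
        for rid in removed_ids:
            row = ensure(_species_of(rid))
            if kept.subfamily != UNASSIGNED:
                row.setdefault(kept.subfamily, 0)
                row[kept.subfamily] += 1
    return counts


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_assignments_tsv(assignments: Sequence[Assignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\tspecies_code\tsubfamily\tbest_score_bits\tmargin_bits\t"
            "ambiguous_flag\n"
        )
        for a in assignments:
            margin = "inf" if math.isinf(a.margin_bits) else f"{a.margin_bits:.6f}"
            fh.write(
                f"{a.seq_id}\t{a.species_code}\t{a.subfamily}\t"
                f"{a.best_score_bits:.6f}\t{margin}\t{str(a.ambiguous_flag).lower()}\n"
            )


def read_assignments_tsv(path: str | Path) -> list[Assignment]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "seq_id":
            raise FormatError(f"{path}: unexpected assignments TSV header")
        for ln in fh:
            if not ln.strip():
                continue
            sid, sp, fam, best, margin, amb = ln.rstrip("\n").split("\t")
            out.append(
                Assignment(sid, sp, fam, float(best), float(margin), amb == "true")
            )
    return out
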