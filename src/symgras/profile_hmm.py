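"""Profile hidden Markov models for subfamily detection.

A profile HMM is estimated from a curated seed alignment (Krogh-style
architecture: one match/insert/delete node per conserved alignment column)
and sequences are scored with the forward algorithm as log-odds bit scores
against a background (null) model:

    bit_score = log2( P(seq | model) / P(seq | background) )

Scoring is *glocal*: the model is always traversed begin-to-end, while the
sequence may have unmodeled flanks. Flanking residues are absorbed by
flanking insert states that emit the background distribution, so their
emissions cancel exactly in the log-odds and flank transitions are scored
at zero bits. This full-domain semantics is a deliberate divergence from
hmmsearch's default local mode: seed alignments are already cropped to the
domain, so a hit should span the whole model.

All probability arithmetic is carried out in log2 space; no scaling-factor
variant is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from symgras.errors import ArgumentError, BuildError, FormatError, ScoringError
from symgras.seqio import AMINO_ACIDS, GAP, MultipleAlignment, ProteinSequence

_NEG_INF = -math.inf
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_N_AA = len(AMINO_ACIDS)

#: transition names: B = begin; per-node M/I/D each with successors M/I/D of
#: the next node (full 9-transition node); the last node's M and D go to END
#: with probability 1 and have no insert state after them.
_TRANSITION_KEYS = ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DI", "DD")


@dataclass(frozen=True)
class BuildParams:
    """Estimation choices for :func:`build_profile_hmm`.

    match_column_gap_threshold
        Columns whose gap fraction is <= this value become match states.
    pseudocount_scheme
        ``laplace`` adds ``pseudocount_weight`` to every count option;
        ``background_scaled`` adds ``20 * weight * background[a]`` instead
        (identical to laplace under a uniform background).
    background_source
        ``uniform`` or ``from_alignment`` (residue frequencies of the seed).
    """

    match_column_gap_threshold: float = 0.5
    pseudocount_scheme: str = "laplace"
    pseudocount_weight: float = 1.0
    background_source: str = "uniform"

    def __post_init__(self) -> None:
        if not 0.0 <= self.match_column_gap_threshold < 1.0:
            raise ArgumentError("match_column_gap_threshold must be in [0,1)")
        if self.pseudocount_weight <= 0:
            raise ArgumentError("pseudocount_weight must be positive")
        if self.pseudocount_scheme not in ("laplace", "background_scaled"):
            raise ArgumentError(f"unknown pseudocount_scheme {self.pseudocount_scheme!r}")
        if self.background_source not in ("uniform", "from_alignment"):
            raise ArgumentError(f"unknown background_source {self.background_source!r}")


@dataclass(frozen=True)
class ScoreRecord:
    """A single (sequence, model) log-odds bit score."""

    seq_id: str
    model_name: str
    bit_score: float


@dataclass
class ProfileHMM:
    """A built profile HMM.

    Arrays are probabilities (not logs): ``match_emissions`` is
    ``(n_match, 20)``, ``insert_emissions`` is ``(n_match - 1, 20)`` (no
    insert state after the last node), transition vectors have length
    ``n_match - 1`` except the scalar begin transitions ``BM``/``BD``.
    """

    name: str
    n_match: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: dict[str, np.ndarray]
    background: np.ndarray
    build_params: BuildParams = field(default_factory=BuildParams)
    match_columns: tuple[int, ...] = ()  # 1-based seed columns, provenance

    def __post_init__(self) -> None:
        self.validate()
        self._log = None

    def validate(self, tol: float = 1e-9) -> None:
        if self.n_match < 1:
            raise BuildError("model must have at least one match state")
        if self.match_emissions.shape != (self.n_match, _N_AA):
            raise BuildError("match_emissions has wrong shape")
        if self.insert_emissions.shape != (max(self.n_match - 1, 0), _N_AA):
            raise BuildError("insert_emissions has wrong shape")
        for mat in (self.match_emissions, self.insert_emissions):
            if mat.size and np.abs(mat.sum(axis=1) - 1.0).max() > tol:
                raise BuildError("emission vector does not sum to 1")
        if abs(self.background.sum() - 1.0) > tol:
            raise BuildError("background does not sum to 1")
        t = self.transitions
        if abs(t["BM"] + t["BD"] - 1.0) > tol:
            raise BuildError("begin transitions do not sum to 1")
        n = self.n_match - 1
        for src in "MID":
            keys = [src + dst for dst in "MID"]
            if n == 0:
                continue
            total = sum(np.asarray(t[k], dtype=float) for k in keys)
            if np.abs(total - 1.0).max() > tol:
                raise BuildError(f"{src}-state transitions do not sum to 1")

    # -- log-odds cache ---------------------------------------------------
    def _log_tables(self) -> dict[str, np.ndarray]:
        if self._log is None:
            with np.errstate(divide="ignore"):
                log = {
                    "lem": np.log2(self.match_emissions / self.background),
                    "lie": np.log2(self.insert_emissions / self.background)
                    if self.n_match > 1
                    else np.zeros((0, _N_AA)),
                }
                for k in ("BM", "BD"):
                    log[k] = float(np.log2(self.transitions[k])) if self.transitions[k] > 0 else _NEG_INF
                for k in _TRANSITION_KEYS:
                    log[k] = np.log2(np.asarray(self.transitions[k], dtype=float))
            self._log = log
        return self._log


def _encode(seq: ProteinSequence) -> np.ndarray:
    """Residues as alphabet indices; X becomes -1 (background emission)."""
    return np.array([_AA_INDEX.get(ch, -1) for ch in seq.residues], dtype=np.int64)


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

def build_profile_hmm(
    msa: MultipleAlignment,
    params: BuildParams | None = None,
    name: str = "model",
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns with gap fraction <= ``params.match_column_gap_threshold``
    become match states; residues in the remaining columns are modeled by
    the insert state of the preceding node (residues before the first or
    after the last match column belong to the unmodeled flanks and are
    ignored). Emissions and transitions are estimated from uniform-weight
    counts plus pseudocounts; ``X`` residues occupy their state for
    transition counting but contribute nothing to emission counts.
    """
    params = params or BuildParams()
    rows = [row for _, row in msa.rows]
    if len(rows) < 2:
        raise BuildError("seed alignment must have at least 2 rows")
    ncol = msa.n_columns
    nrow = len(rows)

    gap_frac = [sum(r[c] == GAP for r in rows) / nrow for c in range(ncol)]
    match_cols = [c for c in range(ncol) if gap_frac[c] <= params.match_column_gap_threshold]
    if not match_cols:
        raise BuildError(
            "no column passes the match-column gap threshold "
            f"({params.match_column_gap_threshold}); raise the threshold"
        )
    m = len(match_cols)

    if params.background_source == "uniform":
        background = np.full(_N_AA, 1.0 / _N_AA)
    else:
        counts = np.zeros(_N_AA)
        for r in rows:
            for ch in r:
                idx = _AA_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
        background = (counts + 1.0) / (counts.sum() + _N_AA)

    if params.pseudocount_scheme == "laplace":
        em_pc = np.full(_N_AA, params.pseudocount_weight)
    else:
        em_pc = _N_AA * params.pseudocount_weight * background

    match_counts = np.zeros((m, _N_AA))
    insert_counts = np.zeros((max(m - 1, 0), _N_AA))
    tb = {"BM": 0.0, "BD": 0.0}
    tc = {k: np.zeros(max(m - 1, 0)) for k in _TRANSITION_KEYS}

    first, last = match_cols[0], match_cols[-1]
    match_pos = {c: j for j, c in enumerate(match_cols)}
    for r in rows:
        # state sequence across nodes, with insert visits in between
        prev_state: str | None = None  # None == begin
        prev_node = -1
        pending_inserts = 0
        for c in range(first, last + 1):
            if c in match_pos:
                j = match_pos[c]
                state = "D" if r[c] == GAP else "M"
                if state == "M":
                    idx = _AA_INDEX.get(r[c])
                    if idx is not None:
                        match_counts[j, idx] += 1
                # transitions from previous node into node j
                if prev_state is None:
                    tb["B" + state] += 1
                else:
                    src = prev_state
                    if pending_inserts:
                        tc[src + "I"][prev_node] += 1
                        tc["II"][prev_node] += pending_inserts - 1
                        src = "I"
                    tc[src + state][prev_node] += 1
                prev_state, prev_node, pending_inserts = state, j, 0
            elif r[c] != GAP and prev_state is not None and prev_node < m - 1:
                pending_inserts += 1
        # trailing inserts after the last match column are flank: ignored

    den = 2 * params.pseudocount_weight
    transitions: dict[str, np.ndarray] = {}
    transitions["BM"] = (tb["BM"] + params.pseudocount_weight) / (nrow + den)
    transitions["BD"] = (tb["BD"] + params.pseudocount_weight) / (nrow + den)
    for src in "MID":
        keys = [src + dst for dst in "MID"]
        totals = sum(tc[k] for k in keys) + 3 * params.pseudocount_weight
        for k in keys:
            transitions[k] = (tc[k] + params.pseudocount_weight) / totals

    match_emissions = (match_counts + em_pc) / (
        match_counts.sum(axis=1, keepdims=True) + em_pc.sum()
    )
    insert_emissions = (insert_counts + em_pc) / (
        insert_counts.sum(axis=1, keepdims=True) + em_pc.sum()
    ) if m > 1 else np.zeros((0, _N_AA))

    return ProfileHMM(
        name=name,
        n_match=m,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
        build_params=params,
        match_columns=tuple(c + 1 for c in match_cols),
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _logaddexp2_chain(b: np.ndarray, step: np.ndarray) -> np.ndarray:
    """Solve x[k] = logaddexp2(x[k-1] + step[k-1], b[k]) for all k.

    Used for the within-position delete chain. ``b`` has length m (entry
    scores into each D state other than via DD), ``step`` has length m-1
    (DD transition scores). Falls back to an explicit loop when a step is
    -inf (forbidden transition), where the cumsum trick breaks down.
    """
    if step.size and not np.all(np.isfinite(step)):
        x = np.empty_like(b)
        x[0] = b[0]
        for k in range(1, len(b)):
            x[k] = np.logaddexp2(x[k - 1] + step[k - 1], b[k])
        return x
    c = np.concatenate(([0.0], np.cumsum(step)))
    with np.errstate(invalid="ignore"):
        y = np.logaddexp2.accumulate(b - c)
    return y + c


def _max_chain(b: np.ndarray, step: np.ndarray) -> np.ndarray:
    if step.size and not np.all(np.isfinite(step)):
        x = np.empty_like(b)
        x[0] = b[0]
        for k in range(1, len(b)):
            x[k] = max(x[k - 1] + step[k - 1], b[k])
        return x
    c = np.concatenate(([0.0], np.cumsum(step)))
    return np.maximum.accumulate(b - c) + c


def _emission_column(table: np.ndarray, x: int) -> np.ndarray:
    """Log-odds emission scores for residue index x (X -> 0 bits)."""
    if x < 0:
        return np.zeros(table.shape[0])
    return table[:, x]


def forward_score(hmm: ProfileHMM, seq: ProteinSequence) -> ScoreRecord:
    """Forward-algorithm log-odds bit score of ``seq`` under ``hmm``.

    Sums over all glocal alignments (all model entry/exit positions in the
    sequence and all match/insert/delete paths through the model) in log2
    space. Deterministic for fixed inputs.
    """
    M, I, D, ends = _dp(hmm, seq, viterbi=False)
    total = ends[0]
    for e in ends[1:]:
        total = np.logaddexp2(total, e)
    return ScoreRecord(seq.id, hmm.name, float(total))


def viterbi_path(hmm: ProfileHMM, seq: ProteinSequence) -> tuple[list[str], float]:
    """Highest-probability single state path and its log-odds bit score.

    The Viterbi score is always <= the forward score. Ties are broken
    preferring match over delete over insert, which makes the returned
    path deterministic.
    """
    M, I, D, ends = _dp(hmm, seq, viterbi=True)
    return _traceback(hmm, seq, M, I, D, ends)


def _dp(hmm: ProfileHMM, seq: ProteinSequence, viterbi: bool):
    if not seq.residues:
        raise ScoringError(f"cannot score empty sequence {seq.id!r}")
    log = hmm._log_tables()
    m = hmm.n_match
    xs = _encode(seq)
    L = len(xs)

    combine = np.maximum if viterbi else np.logaddexp2
    chain = _max_chain if viterbi else _logaddexp2_chain

    M = np.full((L + 1, m), _NEG_INF)
    I = np.full((L + 1, max(m - 1, 0)), _NEG_INF)
    D = np.full((L + 1, m), _NEG_INF)

    dd = log["DD"] if m > 1 else np.zeros(0)

    # position 0: only begin -> delete chain is reachable
    b0 = np.full(m, _NEG_INF)
    b0[0] = log["BD"]
    D[0] = chain(b0, dd)

    for i in range(1, L + 1):
        x = xs[i - 1]
        em = _emission_column(log["lem"], x)
        newM = np.full(m, _NEG_INF)
        newM[0] = log["BM"]  # begin reachable at zero cost before any residue
        if m > 1:
            prev = combine(
                combine(M[i - 1, :-1] + log["MM"], I[i - 1] + log["IM"]),
                D[i - 1, :-1] + log["DM"],
            )
            newM[1:] = prev
        newM += em
        M[i] = newM

        if m > 1:
            ie = _emission_column(log["lie"], x)
            I[i] = ie + combine(
                combine(M[i - 1, :-1] + log["MI"], I[i - 1] + log["II"]),
                D[i - 1, :-1] + log["DI"],
            )

        b = np.full(m, _NEG_INF)
        b[0] = log["BD"]
        if m > 1:
            b[1:] = combine(M[i, :-1] + log["MD"], I[i] + log["ID"])
        D[i] = chain(b, dd)

    ends = combine(M[:, m - 1], D[:, m - 1])  # exit to END costs 0 bits
    return M, I, D, ends


def _traceback(hmm, seq, M, I, D, ends) -> tuple[list[str], float]:
    log = hmm._log_tables()
    m = hmm.n_match
    xs = _encode(seq)
    score = float(np.max(ends))
    tol = 1e-9

    def close(a: float, b: float) -> bool:
        return a > _NEG_INF and abs(a - b) <= tol

    # end position: prefer an exit through a match state (M > D tie rule),
    # then the smallest tied position
    tied = [j for j in range(len(ends)) if close(ends[j], score)]
    match_tied = [j for j in tied if close(M[j, m - 1], score)]
    i = (match_tied or tied)[0]
    state = "M" if close(M[i, m - 1], score) else "D"
    k = m - 1
    path: list[str] = []
    while True:
        path.append(f"{state}{k + 1}")
        if state == "M":
            em = _emission_column(log["lem"], xs[i - 1])[k]
            target = M[i, k] - em
            i -= 1
            if k == 0:
                break
            cands = [
                ("M", M[i, k - 1] + log["MM"][k - 1]),
                ("D", D[i, k - 1] + log["DM"][k - 1]),
                ("I", I[i, k - 1] + log["IM"][k - 1]),
            ]
            k -= 1
        elif state == "D":
            target = D[i, k]
            if k == 0:
                break
            cands = [
                ("M", M[i, k - 1] + log["MD"][k - 1]),
                ("D", D[i, k - 1] + log["DD"][k - 1]),
                ("I", I[i, k - 1] + log["ID"][k - 1]),
            ]
            k -= 1
        else:  # insert at node k+1 (between match k+1 and k+2)
            ie = _emission_column(log["lie"], xs[i - 1])[k]
            target = I[i, k] - ie
            i -= 1
            cands = [
                ("M", M[i, k] + log["MI"][k]),
                ("D", D[i, k] + log["DI"][k]),
                ("I", I[i, k] + log["II"][k]),
            ]
        for st, val in cands:  # order encodes the M > D > I tie rule
            if close(val, target):
                state = st
                break
        else:  # pragma: no cover - DP/traceback inconsistency safety net
            break
    path.append("begin")
    path.reverse()
    path.append("end")
    return path, score


def score_sequences(
    hmms: Iterable[ProfileHMM], seqs: Sequence[ProteinSequence]
) -> list[ScoreRecord]:
    """Score every sequence against every model."""
    records = []
    for hmm in hmms:
        for seq in seqs:
            records.append(forward_score(hmm, seq))
    return records


# ---------------------------------------------------------------------------
# Serialization (own plain-text dialect; HMMER3 .hmm files are NOT read)
# ---------------------------------------------------------------------------

_MAGIC = "symgras-hmm/1"


def _fmt(values) -> str:
    return " ".join(f"{v:.12g}" for v in np.atleast_1d(values))


def write_hmm(hmm: ProfileHMM, path: str | Path) -> None:
    """Write a model in the package's versioned key/value text format.

    Round-trips through :func:`read_hmm` exactly to 12 significant digits.
    """
    p = hmm.build_params
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\n")
        fh.write(f"name {hmm.name}\n")
        fh.write(f"n_match {hmm.n_match}\n")
        fh.write(f"alphabet {AMINO_ACIDS}\n")
        fh.write(
            "build_params "
            f"match_column_gap_threshold={p.match_column_gap_threshold:.12g} "
            f"pseudocount_scheme={p.pseudocount_scheme} "
            f"pseudocount_weight={p.pseudocount_weight:.12g} "
            f"background_source={p.background_source}\n"
        )
        if hmm.match_columns:
            fh.write("match_columns " + " ".join(map(str, hmm.match_columns)) + "\n")
        fh.write(f"background {_fmt(hmm.background)}\n")
        for j in range(hmm.n_match):
            fh.write(f"match {j + 1} {_fmt(hmm.match_emissions[j])}\n")
        for j in range(hmm.n_match - 1):
            fh.write(f"insert {j + 1} {_fmt(hmm.insert_emissions[j])}\n")
        for key in ("BM", "BD"):
            fh.write(f"trans {key} {_fmt(hmm.transitions[key])}\n")
        for key in _TRANSITION_KEYS:
            fh.write(f"trans {key} {_fmt(hmm.transitions[key])}\n")
        fh.write("end\n")


def read_hmm(path: str | Path) -> ProfileHMM:
    """Read a model written by :func:`write_hmm`."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or lines[0] != _MAGIC:
        raise FormatError(f"{path}: not a {_MAGIC} file")
    fields: dict[str, str] = {}
    match_rows: dict[int, np.ndarray] = {}
    insert_rows: dict[int, np.ndarray] = {}
    trans: dict[str, np.ndarray] = {}
    for ln in lines[1:]:
        if ln == "end":
            break
        key, _, rest = ln.partition(" ")
        if key == "match" or key == "insert":
            idx_s, _, vals = rest.partition(" ")
            row = np.array([float(v) for v in vals.split()])
            (match_rows if key == "match" else insert_rows)[int(idx_s)] = row
        elif key == "trans":
            tkey, _, vals = rest.partition(" ")
            arr = np.array([float(v) for v in vals.split()])
            trans[tkey] = arr
        else:
            fields[key] = rest
    try:
        n_match = int(fields["n_match"])
        bp_tokens = dict(tok.split("=", 1) for tok in fields["build_params"].split())
        params = BuildParams(
            match_column_gap_threshold=float(bp_tokens["match_column_gap_threshold"]),
            pseudocount_scheme=bp_tokens["pseudocount_scheme"],
            pseudocount_weight=float(bp_tokens["pseudocount_weight"]),
            background_source=bp_tokens["background_source"],
        )
        background = np.array([float(v) for v in fields["background"].split()])
        match_emissions = np.vstack([match_rows[j + 1] for j in range(n_match)])
        insert_emissions = (
            np.vstack([insert_rows[j + 1] for j in range(n_match - 1)])
            if n_match > 1
            else np.zeros((0, _N_AA))
        )
        transitions = {k: (float(v[0]) if k in ("BM", "BD") else v) for k, v in trans.items()}
        match_columns = tuple(
            int(v) for v in fields.get("match_columns", "").split()
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed model file ({exc})") from exc
    return ProfileHMM(
        name=fields.get("name", path.stem),
        n_match=n_match,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
        build_params=params,
        match_columns=match_columns,
    )


def write_scores_tsv(records: Sequence[ScoreRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tmodel_name\tbit_score\n")
        for r in records:
            fh.write(f"{r.seq_id}\t{r.model_name}\t{r.bit_score:.6f}\n")


def read_scores_tsv(path: str | Path) -> list[ScoreRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["seq_id", "model_name", "bit_score"]:
            raise FormatError(f"{path}: unexpected score TSV header {header}")
        for ln in fh:
            if not ln.strip():
                continue
            sid, model, bits = ln.rstrip("\n").split("\t")
            records.append(ScoreRecord(sid, model, float(bits)))
    return records
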