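"""Copy-number tabulation and loss/expansion reconstruction on a species tree.

Two reconstructions are provided:

* :func:`dollo_reconstruct` — presence/absence under Dollo parsimony: each
  subfamily is gained at most once (by default at the root, implementing
  the conclusion that the land-plant ancestor carried the full set of
  symbiotic GRAS subfamilies) and only losses are inferred, placed on the
  shallowest (rootmost) branches that explain every absent leaf.
* :func:`copy_number_parsimony` — Sankoff parsimony over ancestral copy
  numbers with unit cost per copy step and regain from zero forbidden;
  branches gaining copies emit *expansion* events (duplications), branches
  dropping to zero emit *loss*, other decreases *contraction*.

Absence observed only in transcriptome data is soft evidence ("absence of
transcripts must not necessarily reflect absence of the gene"); such cells
can be treated as missing data and marginalized out of both reconstructions.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from symgras.clade_tools import SUBFAMILIES
from symgras.errors import ArgumentError, DataError, FormatError
from symgras.classify import Assignment, tabulate_counts

GENOME = "genome"
TRANSCRIPTOME = "transcriptome"


@dataclass
class CopyNumberMatrix:
    """Species x subfamily gene counts with per-cell evidence tiers."""

    species: list[str]
    subfamilies: list[str]
    counts: np.ndarray  # (n_species, n_subfamilies) non-negative ints
    evidence: np.ndarray | None = None  # same shape, 'genome'/'transcriptome'

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.species), len(self.subfamilies)):
            raise ArgumentError("counts shape does not match species x subfamilies")
        if (self.counts < 0).any():
            raise ArgumentError("counts must be non-negative")
        if self.evidence is None:
            self.evidence = np.full(self.counts.shape, GENOME, dtype=object)
        self.evidence = np.asarray(self.evidence, dtype=object)
        if self.evidence.shape != self.counts.shape:
            raise ArgumentError("evidence shape does not match counts")

    def count(self, species: str, subfamily: str) -> int:
        return int(self.counts[self._si(species), self._fi(subfamily)])

    def tier(self, species: str, subfamily: str) -> str:
        return str(self.evidence[self._si(species), self._fi(subfamily)])

    def _si(self, species: str) -> int:
        try:
            return self.species.index(species)
        except ValueError:
            raise ArgumentError(f"unknown species {species!r}")

    def _fi(self, subfamily: str) -> int:
        try:
            return self.subfamilies.index(subfamily)
        except ValueError:
            raise ArgumentError(f"unknown subfamily {subfamily!r}")

    def presence(self) -> np.ndarray:
        return self.counts > 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\t" + "\t".join(self.subfamilies) + "\n")
            for i, sp in enumerate(self.species):
                fh.write(sp + "\t" + "\t".join(str(c) for c in self.counts[i]) + "\n")

    def evidence_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\t" + "\t".join(self.subfamilies) + "\n")
            for i, sp in enumerate(self.species):
                fh.write(sp + "\t" + "\t".join(self.evidence[i]) + "\n")

    @classmethod
    def read_tsv(
        cls, path: str | Path, evidence_path: str | Path | None = None
    ) -> "CopyNumberMatrix":
        species, rows = [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "species":
                raise FormatError(f"{path}: first column must be 'species'")
            subfamilies = header[1:]
            for ln in fh:
                if not ln.strip():
                    continue
                parts = ln.rstrip("\n").split("\t")
                species.append(parts[0])
                rows.append([int(v) for v in parts[1:]])
        counts = np.array(rows, dtype=int) if rows else np.zeros((0, len(subfamilies)), int)
        evidence = None
        if evidence_path is not None:
            ev_rows = []
            with open(evidence_path) as fh:
                fh.readline()
                for ln in fh:
                    if ln.strip():
                        ev_rows.append(ln.rstrip("\n").split("\t")[1:])
            evidence = np.array(ev_rows, dtype=object)
        return cls(species, list(subfamilies), counts, evidence)


@dataclass(frozen=True)
class BranchEvent:
    """One inferred event on the branch above the named child node."""

    branch: str  # child-node label
    subfamily: str
    event: str  # loss | gain | expansion | contraction
    copy_change: int


@dataclass
class EventReconstruction:
    """Per-branch events plus ancestral states on a labeled species tree."""

    branch_events: list[BranchEvent]
    ancestral_states: dict[str, dict[str, int]]  # node label -> subfamily -> copies
    total_cost: int
    n_cooptimal: int = 1

    def events_for(self, subfamily: str) -> list[BranchEvent]:
        return [e for e in self.branch_events if e.subfamily == subfamily]


# ---------------------------------------------------------------------------
# tree helpers
# ---------------------------------------------------------------------------

def ensure_node_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign deterministic labels (N1, N2, ...) to unlabeled internal nodes."""
    existing = {n.label for n in tree.preorder_node_iter() if n.label}
    existing |= {l.taxon.label for l in tree.leaf_node_iter()}
    counter = 1
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.label is None:
                node.label = node.taxon.label
        elif not node.label:
            while f"N{counter}" in existing:
                counter += 1
            node.label = f"N{counter}"
            existing.add(node.label)
    return tree


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


def _check_rooted(tree: dendropy.Tree) -> None:
    if not tree.is_rooted:
        raise DataError("species tree must be rooted")
    if len(tree.seed_node.child_nodes()) < 2 and len(tree.leaf_nodes()) > 1:
        raise DataError("rooted tree root must have at least two children")


# ---------------------------------------------------------------------------
# copy matrix
# ---------------------------------------------------------------------------

def build_copy_matrix(
    assignments: Sequence[Assignment],
    species_tree: dendropy.Tree,
    evidence_map: Mapping[str, str] | None = None,
    removed_map: Mapping[str, Sequence[str]] | None = None,
    subfamilies: Sequence[str] = SUBFAMILIES,
) -> CopyNumberMatrix:
    """Tabulate per-species subfamily counts over the species-tree leaves.

    Species present in the tree but absent from the assignments get
    all-zero rows; the evidence tier of every cell in a species row comes
    from ``evidence_map`` (default ``genome``). Row order follows the tree's
    leaf order; column order is the configured subfamily order.
    """
    from symgras.clade_tools import leaf_labels

    tree_species = leaf_labels(species_tree)
    counts_all = tabulate_counts(assignments, removed_map, subfamilies)
    unknown = sorted(set(counts_all) - set(tree_species))
    if unknown:
        raise DataError(
            f"assignment species missing from the species tree: {unknown}"
        )
    evidence_map = dict(evidence_map or {})
    fams = list(subfamilies)
    extra = sorted(
        {f for row in counts_all.values() for f, c in row.items() if c and f not in fams}
    )
    fams = fams + extra
    counts = np.zeros((len(tree_species), len(fams)), dtype=int)
    evidence = np.full(counts.shape, GENOME, dtype=object)
    for i, sp in enumerate(tree_species):
        row = counts_all.get(sp, {})
        for j, fam in enumerate(fams):
            counts[i, j] = row.get(fam, 0)
        tier = evidence_map.get(sp, GENOME)
        if tier not in (GENOME, TRANSCRIPTOME):
            raise ArgumentError(f"unknown evidence tier {tier!r} for {sp}")
        evidence[i, :] = tier
    return CopyNumberMatrix(list(tree_species), fams, counts, evidence)


# ---------------------------------------------------------------------------
# Dollo reconstruction
# ---------------------------------------------------------------------------

def dollo_reconstruct(
    matrix: CopyNumberMatrix,
    species_tree: dendropy.Tree,
    root_state: str = "present",
    transcriptome_absence_as_missing: bool = False,
) -> EventReconstruction:
    """Minimum-loss Dollo reconstruction of presence/absence.

    With ``root_state='present'`` every subfamily observed in at least one
    leaf is gained once at the root and only losses are placed, on the
    shallowest branches whose entire subtree lacks the subfamily. With
    ``'infer'`` the gain is placed on the MRCA of the present leaves and
    counted in the cost. Soft (transcriptome-tier) absences can be treated
    as missing data and are then never used to justify a loss.
    """
    if root_state not in ("present", "infer"):
        raise ArgumentError("root_state must be 'present' or 'infer'")
    _check_rooted(species_tree)
    ensure_node_labels(species_tree)
    from symgras.clade_tools import leaf_labels

    tree_sp = leaf_labels(species_tree)
    missing_sp = sorted(set(matrix.species) ^ set(tree_sp))
    if missing_sp:
        raise DataError(f"matrix species and tree leaves differ: {missing_sp}")

    events: list[BranchEvent] = []
    states: dict[str, dict[str, int]] = {}
    total = 0
    for fam in matrix.subfamilies:
        present_leaves = set()
        hard_absent = set()
        for sp in matrix.species:
            c = matrix.count(sp, fam)
            if c > 0:
                present_leaves.add(sp)
            elif transcriptome_absence_as_missing and matrix.tier(sp, fam) == TRANSCRIPTOME:
                pass  # missing data: marginalized
            else:
                hard_absent.add(sp)

        has_present: dict[dendropy.Node, bool] = {}
        has_hard_absent: dict[dendropy.Node, bool] = {}
        for node in species_tree.postorder_node_iter():
            if node.is_leaf():
                lbl = node.taxon.label
                has_present[node] = lbl in present_leaves
                has_hard_absent[node] = lbl in hard_absent
            else:
                kids = node.child_nodes()
                has_present[node] = any(has_present[k] for k in kids)
                has_hard_absent[node] = any(has_hard_absent[k] for k in kids)

        if root_state == "infer" and present_leaves:
            gain_node = species_tree.mrca(
                taxa=[species_tree.taxon_namespace.get_taxon(s) for s in present_leaves]
            ) if len(present_leaves) > 1 else next(
                l for l in species_tree.leaf_node_iter()
                if l.taxon.label in present_leaves
            )
            events.append(BranchEvent(_node_label(gain_node), fam, "gain", +1))
            total += 1
            in_gained = set(gain_node.preorder_iter())
        else:
            gain_node = species_tree.seed_node if present_leaves else None
            in_gained = set(species_tree.preorder_node_iter()) if present_leaves else set()

        for node in species_tree.preorder_node_iter():
            lbl = _node_label(node)
            present_here = node in in_gained and has_present[node]
            states.setdefault(lbl, {})[fam] = 1 if present_here else 0
            parent = node.parent_node
            if (
                node in in_gained
                and not has_present[node]
                and has_hard_absent[node]
                and parent is not None
                and parent in in_gained
                and has_present[parent]
            ):
                events.append(BranchEvent(lbl, fam, "loss", -1))
                total += 1

        # leaves report their observed state regardless of marginalization
        for sp in matrix.species:
            states[sp][fam] = 1 if sp in present_leaves else 0

    return EventReconstruction(events, states, total)


# ---------------------------------------------------------------------------
# Sankoff copy-number parsimony
# ---------------------------------------------------------------------------

def copy_number_parsimony(
    matrix: CopyNumberMatrix,
    species_tree: dendropy.Tree,
    max_count: int | None = None,
    dollo: bool = True,
    transcriptome_absence_as_missing: bool = False,
) -> EventReconstruction:
    """Minimum-cost ancestral copy numbers (Sankoff, unit cost per step).

    The state space is ``0..max(observed)`` (or ``max_count``); branch cost
    is ``|parent - child|`` with regain from zero forbidden when ``dollo``
    is set. Ties in the backtrace prefer placing the change on the
    rootward branch (a single deep event over repeated shallow ones);
    ``n_cooptimal`` reports the exact number of equally parsimonious
    ancestral labelings.
    """
    _check_rooted(species_tree)
    ensure_node_labels(species_tree)
    from symgras.clade_tools import leaf_labels

    tree_sp = leaf_labels(species_tree)
    diff = sorted(set(matrix.species) ^ set(tree_sp))
    if diff:
        raise DataError(f"matrix species and tree leaves differ: {diff}")

    observed_max = int(matrix.counts.max()) if matrix.counts.size else 0
    if max_count is not None and observed_max > max_count:
        i, j = np.unravel_index(int(matrix.counts.argmax()), matrix.counts.shape)
        raise DataError(
            f"count {observed_max} for ({matrix.species[i]}, "
            f"{matrix.subfamilies[j]}) exceeds max_count={max_count}"
        )
    n_states = max(observed_max, 1) + 1
    states_range = np.arange(n_states)

    # branch cost matrix T[a, b]
    T = np.abs(states_range[:, None] - states_range[None, :]).astype(float)
    if dollo:
        T[0, 1:] = math.inf

    events: list[BranchEvent] = []
    anc: dict[str, dict[str, int]] = {}
    grand_total = 0
    n_coopt = 1
    postorder = list(species_tree.postorder_node_iter())
    for fam in matrix.subfamilies:
        cost: dict[dendropy.Node, np.ndarray] = {}
        count_dp: dict[dendropy.Node, np.ndarray] = {}
        for node in postorder:
            if node.is_leaf():
                sp = node.taxon.label
                c = matrix.count(sp, fam)
                vec = np.full(n_states, math.inf)
                if (
                    c == 0
                    and transcriptome_absence_as_missing
                    and matrix.tier(sp, fam) == TRANSCRIPTOME
                ):
                    vec[:] = 0.0  # missing data: any state allowed
                else:
                    vec[c] = 0.0
                cost[node] = vec
                count_dp[node] = np.where(np.isfinite(vec), 1.0, 0.0)
            else:
                vec = np.zeros(n_states)
                wcount = np.ones(n_states)
                for kid in node.child_nodes():
                    # for each parent state a: min_b T[a,b] + cost[kid][b]
                    through = T + cost[kid][None, :]
                    best = through.min(axis=1)
                    vec += best
                    with np.errstate(invalid="ignore"):
                        ties = np.isclose(through, best[:, None]) & np.isfinite(through)
                    wcount *= (ties * count_dp[kid][None, :]).sum(axis=1)
                cost[node] = vec
                count_dp[node] = wcount

        root = species_tree.seed_node
        root_cost = cost[root]
        best_total = float(root_cost.min())
        if not math.isfinite(best_total):
            raise DataError(f"no finite-cost reconstruction for {fam}")
        root_ties = np.isclose(root_cost, best_total)
        n_coopt *= int(count_dp[root][root_ties].sum())
        root_state = int(np.flatnonzero(root_ties)[0])  # smallest tied state
        grand_total += int(round(best_total))

        chosen: dict[dendropy.Node, int] = {root: root_state}
        for node in reversed(postorder):  # parents before children
            a = chosen[node]
            anc.setdefault(_node_label(node), {})[fam] = a
            for kid in node.child_nodes():
                through = T[a] + cost[kid]
                best = through.min()
                tied = [int(b) for b in np.flatnonzero(np.isclose(through, best))]
                # rootward placement: largest |b - a| first, then smaller b
                tied.sort(key=lambda b: (-abs(b - a), b))
                b = tied[0]
                chosen[kid] = b
                delta = b - a
                if delta > 0:
                    events.append(BranchEvent(_node_label(kid), fam, "expansion", delta))
                elif delta < 0:
                    kind = "loss" if b == 0 else "contraction"
                    events.append(BranchEvent(_node_label(kid), fam, kind, delta))

    return EventReconstruction(events, anc, grand_total, n_coopt)


# ---------------------------------------------------------------------------
# combined events and report
# ---------------------------------------------------------------------------

def reconstruct_events(
    matrix: CopyNumberMatrix,
    species_tree: dendropy.Tree,
    root_state: str = "present",
    transcriptome_absence_as_missing: bool = False,
) -> EventReconstruction:
    """Dollo losses/gains combined with Sankoff expansions/contractions.

    Presence-level events (gain, loss) come from :func:`dollo_reconstruct`;
    copy-number changes among retained lineages (expansion, contraction)
    come from :func:`copy_number_parsimony`. Ancestral states are the
    Sankoff copy numbers.
    """
    dollo = dollo_reconstruct(
        matrix, species_tree, root_state, transcriptome_absence_as_missing
    )
    sankoff = copy_number_parsimony(
        matrix, species_tree,
        transcriptome_absence_as_missing=transcriptome_absence_as_missing,
    )
    events = list(dollo.branch_events) + [
        e for e in sankoff.branch_events if e.event in ("expansion", "contraction")
    ]
    total = sum(abs(e.copy_change) for e in events)
    return EventReconstruction(
        events, sankoff.ancestral_states, total,
        n_cooptimal=sankoff.n_cooptimal,
    )


@dataclass
class EventReport:
    """Human-readable and tabular summary of a reconstruction."""

    recon: EventReconstruction
    matrix: CopyNumberMatrix
    soft_absences: list[tuple[str, str]] = field(default_factory=list)

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write("Per-branch events\n")
        if not self.recon.branch_events:
            buf.write("  no events inferred\n")
        else:
            for e in sorted(
                self.recon.branch_events, key=lambda e: (e.subfamily, e.branch)
            ):
                buf.write(
                    f"  {e.branch}: {e.subfamily} {e.event} "
                    f"({e.copy_change:+d})\n"
                )
        buf.write(f"Total event cost: {self.recon.total_cost}\n")
        if self.recon.n_cooptimal > 1:
            buf.write(
                f"Co-optimal reconstructions: {self.recon.n_cooptimal}\n"
            )
        buf.write("\nPer-species complements\n")
        for i, sp in enumerate(self.matrix.species):
            cells = ", ".join(
                f"{fam}={self.matrix.counts[i, j]}"
                for j, fam in enumerate(self.matrix.subfamilies)
            )
            buf.write(f"  {sp}: {cells}\n")
        if self.soft_absences:
            buf.write("\nSoft absences (transcriptome-only; absence not conclusive)\n")
            for sp, fam in self.soft_absences:
                buf.write(f"  {sp}: {fam}\n")
        return buf.getvalue()

    def events_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("branch\tsubfamily\tevent\tcopy_change\n")
            for e in sorted(
                self.recon.branch_events, key=lambda e: (e.subfamily, e.branch)
            ):
                fh.write(f"{e.branch}\t{e.subfamily}\t{e.event}\t{e.copy_change}\n")


def event_report(recon: EventReconstruction, matrix: CopyNumberMatrix) -> EventReport:
    """Build the event report, flagging transcriptome-only absences as soft."""
    soft = [
        (sp, fam)
        for i, sp in enumerate(matrix.species)
        for j, fam in enumerate(matrix.subfamilies)
        if matrix.counts[i, j] == 0 and matrix.evidence[i, j] == TRANSCRIPTOME
    ]
    return EventReport(recon, matrix, soft)
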