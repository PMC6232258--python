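"""Fully labeled synthetic datasets for pipeline testing.

The generator instantiates exactly the statistical structure the analysis
assumes: a rooted species tree, per-subfamily gene histories evolving from
a single copy at the root by branch-wise loss and duplication, protein
sequences emitted from subfamily-specific position-specific residue
profiles with per-branch substitution noise and indels, background decoy
sequences, seed alignments with known column correspondence, and a
reference gene tree with a basally attached outgroup pair (named GAI/RGA
after the DELLA sequences conventionally used for rooting).

Sequences are generated column-wise from profiles rather than by a
substitution-matrix Markov process along the gene tree; this is a
deliberate simplification: clade-specific profiles are precisely the
assumption the classifier relies on, and the true alignment falls out for
free. Every output is deterministic per seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from symgras.clade_tools import CladeDefinition, write_clades_tsv, write_tree
from symgras.errors import ArgumentError
from symgras.evolution import BranchEvent, CopyNumberMatrix, ensure_node_labels
from symgras.seqio import AMINO_ACIDS, GAP, MultipleAlignment, ProteinSequence, write_alignment, write_fasta

_N_AA = len(AMINO_ACIDS)

#: ids of the two outgroup sequences attached basally to the gene tree
OUTGROUP_IDS = ("ARATH_GAI", "ARATH_RGA")
_OUTGROUP_PROFILE = "OUTGROUP"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``conservation`` concentrates each profile column on a column-specific
    consensus residue with weight ``c / (1 + c)``: 0 reproduces the
    background exactly and the limit of large values degenerates each
    column to a single residue.
    """

    n_species: int = 20
    subfamilies: tuple[str, ...] = ("NSP1", "NSP2", "RAM1", "RAD1")
    domain_length: int = 120
    conservation: float = 9.0
    per_branch_substitution_prob: float = 0.03
    per_branch_loss_prob: float = 0.05
    per_branch_duplication_prob: float = 0.05
    n_decoys_per_species: int = 5
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ArgumentError("n_species must be >= 2")
        if self.domain_length < 1:
            raise ArgumentError("domain_length must be positive")
        for name in (
            "per_branch_substitution_prob",
            "per_branch_loss_prob",
            "per_branch_duplication_prob",
            "indel_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ArgumentError(f"{name} must be in [0,1)")
        if self.conservation < 0:
            raise ArgumentError("conservation must be non-negative")
        if self.n_decoys_per_species < 0:
            raise ArgumentError("n_decoys_per_species must be >= 0")
        if not self.subfamilies:
            raise ArgumentError("at least one subfamily required")


@dataclass
class SyntheticTruth:
    """Ground truth labels, copy numbers and event placements."""

    true_subfamily: dict[str, str]  # seq_id -> subfamily or 'decoy'
    true_copy_matrix: CopyNumberMatrix
    true_events: list[BranchEvent]
    species_tree: dendropy.Tree
    gene_trees: dict[str, dendropy.Tree]


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset; ``write`` materializes it as text files."""

    config: SimulationConfig
    sequences_by_species: dict[str, list[ProteinSequence]]
    seed_alignments: dict[str, MultipleAlignment]
    gene_tree: dendropy.Tree  # combined reference tree with outgroup
    outgroup_sequences: list[ProteinSequence]
    clades: list[CladeDefinition]
    truth: SyntheticTruth
    retries: dict[str, int] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.sequences_by_species)

    def all_candidate_sequences(self) -> list[ProteinSequence]:
        out = []
        for sp in self.sequences_by_species:
            out.extend(self.sequences_by_species[sp])
        return out

    def write(self, out_dir: str | Path) -> dict[str, str]:
        """Write all artifacts plus a manifest; byte-identical per seed."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "proteomes").mkdir(exist_ok=True)
        (out_dir / "seeds").mkdir(exist_ok=True)
        files: dict[str, str] = {}
        for sp, seqs in self.sequences_by_species.items():
            p = out_dir / "proteomes" / f"{sp}.fasta"
            write_fasta(seqs, p)
            files[f"proteome:{sp}"] = str(p.relative_to(out_dir))
        for fam, msa in self.seed_alignments.items():
            p = out_dir / "seeds" / f"{fam}.fasta"
            write_alignment(msa, p)
            files[f"seed:{fam}"] = str(p.relative_to(out_dir))
        write_fasta(self.outgroup_sequences, out_dir / "outgroup.fasta")
        files["outgroup"] = "outgroup.fasta"
        write_tree(self.truth.species_tree, out_dir / "species_tree.nwk")
        files["species_tree"] = "species_tree.nwk"
        write_tree(self.gene_tree, out_dir / "gene_tree.nwk")
        files["gene_tree"] = "gene_tree.nwk"
        write_clades_tsv(self.clades, out_dir / "clades.tsv")
        files["clades"] = "clades.tsv"
        with open(out_dir / "truth_subfamily.tsv", "w") as fh:
            fh.write("seq_id\tsubfamily\n")
            for sid in sorted(self.truth.true_subfamily):
                fh.write(f"{sid}\t{self.truth.true_subfamily[sid]}\n")
        files["truth_subfamily"] = "truth_subfamily.tsv"
        self.truth.true_copy_matrix.to_tsv(out_dir / "truth_copy_matrix.tsv")
        files["truth_copy_matrix"] = "truth_copy_matrix.tsv"
        with open(out_dir / "truth_events.tsv", "w") as fh:
            fh.write("branch\tsubfamily\tevent\tcopy_change\n")
            for e in self.truth.true_events:
                fh.write(f"{e.branch}\t{e.subfamily}\t{e.event}\t{e.copy_change}\n")
        files["truth_events"] = "truth_events.tsv"
        import yaml

        manifest = {
            "config": asdict(self.config),
            "seed": self.config.seed,
            "retries": dict(self.retries),
            "files": files,
        }
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        return files


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def _species_codes(n: int, rng: np.random.Generator) -> list[str]:
    letters = np.array(list(string.ascii_uppercase))
    codes: list[str] = []
    seen = set()
    while len(codes) < n:
        code = "".join(rng.choice(letters, size=5))
        if code not in seen and not code.startswith("ARATH"):
            seen.add(code)
            codes.append(code)
    return codes


def simulate_species_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Rooted binary tree from a pure-birth (Yule) process.

    Leaves carry generated five-letter species codes; internal nodes are
    labeled deterministically. Branch lengths are exponential draws (mean
    0.1) and purely decorative for the downstream analysis, which is
    topology-driven.
    """
    if n_species < 2:
        raise ArgumentError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    root = tree.seed_node
    leaves = []
    for _ in range(2):
        child = root.new_child()
        leaves.append(child)
    while len(leaves) < n_species:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        for _ in range(2):
            leaves.append(node.new_child())
    codes = _species_codes(n_species, rng)
    # leaf order: deterministic traversal order
    for leaf, code in zip(tree.leaf_node_iter(), codes):
        taxon = taxon_namespace.new_taxon(code)
        leaf.taxon = taxon
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(np.round(rng.exponential(0.1), 6))
    ensure_node_labels(tree)
    return tree


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def simulate_subfamily_profiles(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    include_outgroup: bool = True,
) -> dict[str, np.ndarray]:
    """Per-subfamily position-specific residue distributions.

    Each column mixes the uniform background with a one-hot distribution on
    a column-specific consensus residue, with mixture weight
    ``conservation / (1 + conservation)``. Distinct subfamilies are drawn
    independently, so higher conservation increases the mean per-column
    total-variation distance between them.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    names = list(config.subfamilies) + ([_OUTGROUP_PROFILE] if include_outgroup else [])
    w = config.conservation / (1.0 + config.conservation)
    bg = np.full(_N_AA, 1.0 / _N_AA)
    profiles = {}
    for name in names:
        cols = np.tile(bg * (1.0 - w), (config.domain_length, 1))
        consensus = rng.integers(0, _N_AA, size=config.domain_length)
        cols[np.arange(config.domain_length), consensus] += w
        profiles[name] = cols
    return profiles


# ---------------------------------------------------------------------------
# gene history + sequences
# ---------------------------------------------------------------------------

class _GeneNode:
    __slots__ = ("children", "label", "seq")

    def __init__(self, seq: np.ndarray, label: str | None = None):
        self.children: list[_GeneNode] = []
        self.label = label
        self.seq = seq


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(out)) < p
    n = int(hit.sum())
    if n:
        out[hit] = rng.integers(0, _N_AA, size=n)
    return out


def _evolve_family(
    species_tree: dendropy.Tree,
    fam: str,
    root_seq: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[_GeneNode | None, dict[str, list[_GeneNode]], list[BranchEvent]]:
    """Evolve one subfamily down the species tree from a single root copy.

    Each copy entering a branch is first exposed to loss, then mutated,
    then exposed to (at most one) duplication; duplicated daughters diverge
    independently over the remainder of the branch and are not themselves
    lost on the same branch.
    """
    events: list[BranchEvent] = []
    leaf_copies: dict[str, list[_GeneNode]] = {
        l.taxon.label: [] for l in species_tree.leaf_node_iter()
    }

    def at_node(sp_node, seq: np.ndarray) -> _GeneNode | None:
        if sp_node.is_leaf():
            code = sp_node.taxon.label
            node = _GeneNode(seq)
            leaf_copies[code].append(node)
            return node
        roots = []
        for child in sp_node.child_nodes():
            r = through_branch(child, seq)
            if r is not None:
                roots.append(r)
        if len(roots) >= 2:
            joint = _GeneNode(seq)
            joint.children = roots
            return joint
        return roots[0] if roots else None

    def through_branch(sp_child, seq: np.ndarray) -> _GeneNode | None:
        branch = sp_child.label if not sp_child.is_leaf() else sp_child.taxon.label
        if rng.random() < config.per_branch_loss_prob:
            events.append(BranchEvent(branch, fam, "loss", -1))
            return None
        seq2 = _mutate(seq, config.per_branch_substitution_prob, rng)
        if rng.random() < config.per_branch_duplication_prob:
            events.append(BranchEvent(branch, fam, "duplication", +1))
            daughters = [
                at_node(
                    sp_child,
                    _mutate(seq2, config.per_branch_substitution_prob, rng),
                )
                for _ in range(2)
            ]
            daughters = [d for d in daughters if d is not None]
            if len(daughters) == 2:
                dup = _GeneNode(seq2)
                dup.children = daughters
                return dup
            return daughters[0] if daughters else None
        return at_node(sp_child, seq2)

    root = at_node(species_tree.seed_node, root_seq)
    for code, copies in leaf_copies.items():
        for i, node in enumerate(copies, start=1):
            node.label = f"{code}_{fam}_{i}"
    return root, leaf_copies, events


def _gene_tree_from(root: _GeneNode, taxon_namespace: dendropy.TaxonNamespace) -> dendropy.Node:
    """Convert the internal gene-node structure to dendropy, suppressing
    unifurcations."""
    while root.children and len(root.children) == 1:
        root = root.children[0]
    node = dendropy.Node()
    if not root.children:
        node.taxon = taxon_namespace.require_taxon(root.label)
    else:
        for child in root.children:
            node.add_child(_gene_tree_from(child, taxon_namespace))
    return node


def _emit_with_indels(
    core: np.ndarray, indel_rate: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Residue string and the aligned (core-column) row for a copy."""
    residues = []
    aligned = []
    for x in core:
        if rng.random() < indel_rate:  # deletion of this column
            aligned.append(GAP)
        else:
            residues.append(AMINO_ACIDS[x])
            aligned.append(AMINO_ACIDS[x])
        if rng.random() < indel_rate:  # insertion after this column
            residues.append(AMINO_ACIDS[int(rng.integers(_N_AA))])
    if not residues:  # degenerate: keep one residue so the record is valid
        residues.append(AMINO_ACIDS[int(core[0])])
        aligned[0] = AMINO_ACIDS[int(core[0])]
    return "".join(residues), "".join(aligned)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a complete labeled dataset under ``config``.

    A subfamily whose simulated history leaves fewer than two surviving
    copies is re-simulated with fresh draws (the dataset conditions on the
    family being observable; retry counts are recorded).
    """
    rng = np.random.default_rng(config.seed)
    species_tree = simulate_species_tree(
        config.n_species, int(rng.integers(2**31 - 1))
    )
    profiles = simulate_subfamily_profiles(config, rng)

    taxon_namespace = dendropy.TaxonNamespace()
    truth_labels: dict[str, str] = {}
    true_events: list[BranchEvent] = []
    sequences_by_species: dict[str, list[ProteinSequence]] = {
        l.taxon.label: [] for l in species_tree.leaf_node_iter()
    }
    seed_alignments: dict[str, MultipleAlignment] = {}
    gene_trees: dict[str, dendropy.Tree] = {}
    counts: dict[str, dict[str, int]] = {
        sp: {} for sp in sequences_by_species
    }
    retries: dict[str, int] = {}
    subtree_roots: list[dendropy.Node] = []

    for fam in config.subfamilies:
        profile = profiles[fam]
        for attempt in range(100):
            root_seq = _sample_profile(profile, rng)
            root, leaf_copies, events = _evolve_family(
                species_tree, fam, root_seq, config, rng
            )
            n_copies = sum(len(v) for v in leaf_copies.values())
            if n_copies >= 2:
                break
            retries[fam] = retries.get(fam, 0) + 1
        else:
            raise ArgumentError(
                f"subfamily {fam} failed to survive simulation; "
                "lower per_branch_loss_prob"
            )
        true_events.extend(events)
        aligned_rows: list[tuple[str, str]] = []
        for sp, copies in leaf_copies.items():
            counts[sp][fam] = len(copies)
            for node in copies:
                residues, aligned = _emit_with_indels(
                    node.seq, config.indel_rate, rng
                )
                seq = ProteinSequence(node.label, residues, "synthetic")
                sequences_by_species[sp].append(seq)
                truth_labels[node.label] = fam
                aligned_rows.append((node.label, aligned))
        # seed alignment: deterministic subset spread over members
        aligned_rows.sort(key=lambda r: r[0])
        step = max(1, len(aligned_rows) // 12)
        seed_rows = aligned_rows[::step][:12]
        if len(seed_rows) < 2:
            seed_rows = aligned_rows[:2]
        seed_alignments[fam] = MultipleAlignment.from_rows(seed_rows)
        # per-family gene tree
        fam_root = _gene_tree_from(root, taxon_namespace)
        subtree_roots.append(fam_root)
        fam_tree = dendropy.Tree(taxon_namespace=taxon_namespace)
        fam_tree.seed_node = _gene_tree_from(root, taxon_namespace)
        fam_tree.is_rooted = True
        ensure_node_labels(fam_tree)
        gene_trees[fam] = fam_tree

    # decoys: background composition, length matched to the domain
    for sp in sequences_by_species:
        for i in range(1, config.n_decoys_per_species + 1):
            length = max(30, int(rng.normal(config.domain_length, 0.05 * config.domain_length)))
            residues = "".join(
                AMINO_ACIDS[j] for j in rng.integers(0, _N_AA, size=length)
            )
            sid = f"{sp}_DECOY_{i}"
            sequences_by_species[sp].append(
                ProteinSequence(sid, residues, "synthetic")
            )
            truth_labels[sid] = "decoy"

    # outgroup pair from an independent profile
    out_profile = profiles[_OUTGROUP_PROFILE]
    outgroup_sequences = []
    for sid in OUTGROUP_IDS:
        core = _sample_profile(out_profile, rng)
        outgroup_sequences.append(
            ProteinSequence(sid, "".join(AMINO_ACIDS[x] for x in core), "synthetic")
        )

    # combined reference gene tree: successively pair subfamily subtrees,
    # then attach the outgroup pair basally
    combined = _pairwise_join(subtree_roots)
    og = dendropy.Node()
    for sid in OUTGROUP_IDS:
        leaf = dendropy.Node()
        leaf.taxon = taxon_namespace.require_taxon(sid)
        og.add_child(leaf)
    top = dendropy.Node()
    top.add_child(combined)
    top.add_child(og)
    gene_tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    gene_tree.seed_node = top
    gene_tree.is_rooted = True
    ensure_node_labels(gene_tree)

    clades = [
        CladeDefinition(
            fam,
            frozenset(s for s, f in truth_labels.items() if f == fam),
        )
        for fam in config.subfamilies
    ]

    species = list(sequences_by_species)
    fams = list(config.subfamilies)
    count_arr = np.array(
        [[counts[sp].get(f, 0) for f in fams] for sp in species], dtype=int
    )
    truth = SyntheticTruth(
        true_subfamily=truth_labels,
        true_copy_matrix=CopyNumberMatrix(
            species, fams, count_arr,
            np.full(count_arr.shape, "genome", dtype=object),
        ),
        true_events=true_events,
        species_tree=species_tree,
        gene_trees=gene_trees,
    )
    return SyntheticDataset(
        config=config,
        sequences_by_species=sequences_by_species,
        seed_alignments=seed_alignments,
        gene_tree=gene_tree,
        outgroup_sequences=outgroup_sequences,
        clades=clades,
        truth=truth,
        retries=retries,
    )


def _sample_profile(profile: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = profile.cumsum(axis=1)
    u = rng.random(profile.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def _pairwise_join(roots: list[dendropy.Node]) -> dendropy.Node:
    nodes = list(roots)
    while len(nodes) > 1:
        paired = []
        for i in range(0, len(nodes) - 1, 2):
            parent = dendropy.Node()
            parent.add_child(nodes[i])
            parent.add_child(nodes[i + 1])
            paired.append(parent)
        if len(nodes) % 2:
            paired.append(nodes[-1])
        nodes = paired
    return nodes[0]


def classification_metrics(
    truth_labels: Mapping[str, str],
    assignments: Sequence,
) -> dict[str, float]:
    """Macro-averaged member accuracy and decoy false-assignment rate.

    Macro accuracy averages, over subfamilies, the fraction of true
    members assigned their exact label; a decoy counts as falsely
    assigned when it receives any subfamily label.
    """
    from symgras.classify import UNASSIGNED

    assigned = {a.seq_id: a.subfamily for a in assignments}
    per_fam: dict[str, list[int]] = {}
    n_decoys = 0
    n_false = 0
    for sid, fam in truth_labels.items():
        got = assigned.get(sid, UNASSIGNED)
        if fam == "decoy":
            n_decoys += 1
            n_false += int(got != UNASSIGNED)
        else:
            per_fam.setdefault(fam, []).append(int(got == fam))
    recalls = [float(np.mean(v)) for v in per_fam.values()]
    return {
        "macro_accuracy": float(np.mean(recalls)) if recalls else float("nan"),
        "decoy_false_rate": (n_false / n_decoys) if n_decoys else 0.0,
        "n_members": int(sum(len(v) for v in per_fam.values())),
        "n_decoys": int(n_decoys),
    }


def copy_cell_recovery(true_matrix: CopyNumberMatrix, observed: CopyNumberMatrix) -> tuple[int, int]:
    """Number of exactly recovered cells and total cells compared."""
    exact = total = 0
    for i, sp in enumerate(true_matrix.species):
        for j, fam in enumerate(true_matrix.subfamilies):
            total += 1
            exact += int(observed.count(sp, fam) == int(true_matrix.counts[i, j]))
    return exact, total


def presence_loss_branches(
    species_tree: dendropy.Tree,
    events: Sequence[BranchEvent],
    subfamilies: Sequence[str],
) -> set[tuple[str, str]]:
    """Branches on which a subfamily's copy count drops to zero.

    These are the presence-level loss branches a Dollo reconstruction of
    the leaf pattern should recover.
    """
    ensure_node_labels(species_tree)
    by_branch: dict[str, dict[str, int]] = {}
    for e in events:
        by_branch.setdefault(e.branch, {}).setdefault(e.subfamily, 0)
        by_branch[e.branch][e.subfamily] += e.copy_change
    losses: set[tuple[str, str]] = set()

    def walk(node, state: dict[str, int]) -> None:
        for child in node.child_nodes():
            label = child.label if not child.is_leaf() else child.taxon.label
            delta = by_branch.get(label, {})
            child_state = {f: state[f] + delta.get(f, 0) for f in subfamilies}
            for f in subfamilies:
                if state[f] > 0 and child_state[f] == 0:
                    losses.add((label, f))
            if not child.is_leaf():
                walk(child, child_state)

    walk(species_tree.seed_node, {f: 1 for f in subfamilies})
    return losses


def loss_branch_recovery(
    config: SimulationConfig,
    n_replicates: int,
    base_seed: int,
) -> tuple[int, int]:
    """Replicated check that Dollo recovers the simulated loss branches.

    For each replicate a fresh gene-content history is simulated under
    ``config`` and :func:`symgras.evolution.dollo_reconstruct` is run on
    the true copy matrix; returns (recovered, total) over all replicated
    presence-loss branches.
    """
    import dataclasses

    from symgras.evolution import dollo_reconstruct

    recovered = total = 0
    for rep in range(n_replicates):
        cfg = dataclasses.replace(
            config, seed=(base_seed + 977 * rep) % (2**31 - 1),
            n_decoys_per_species=0, indel_rate=0.0,
        )
        ds = simulate_dataset(cfg)
        true_losses = presence_loss_branches(
            ds.truth.species_tree, ds.truth.true_events, cfg.subfamilies
        )
        recon = dollo_reconstruct(ds.truth.true_copy_matrix, ds.truth.species_tree)
        inferred = {
            (e.branch, e.subfamily)
            for e in recon.branch_events
            if e.event == "loss"
        }
        total += len(true_losses)
        recovered += len(true_losses & inferred)
    return recovered, total


def replay_events(
    species_tree: dendropy.Tree,
    events: Sequence[BranchEvent],
    subfamilies: Sequence[str],
) -> CopyNumberMatrix:
    """Replay per-branch events from a single-copy root to leaf counts.

    Serves as the internal consistency oracle for
    :func:`simulate_dataset`: the result must equal the generator's
    ``true_copy_matrix`` exactly.
    """
    ensure_node_labels(species_tree)
    by_branch: dict[str, dict[str, int]] = {}
    for e in events:
        by_branch.setdefault(e.branch, {}).setdefault(e.subfamily, 0)
        by_branch[e.branch][e.subfamily] += e.copy_change
    leaves = [l.taxon.label for l in species_tree.leaf_node_iter()]
    counts = np.zeros((len(leaves), len(subfamilies)), dtype=int)

    def walk(node, state: dict[str, int]) -> None:
        for child in node.child_nodes():
            label = child.label if not child.is_leaf() else child.taxon.label
            delta = by_branch.get(label, {})
            child_state = {
                f: state[f] + delta.get(f, 0) for f in subfamilies
            }
            if child.is_leaf():
                i = leaves.index(child.taxon.label)
                for j, f in enumerate(subfamilies):
                    counts[i, j] = child_state[f]
            else:
                walk(child, child_state)

    walk(species_tree.seed_node, {f: 1 for f in subfamilies})
    return CopyNumberMatrix(leaves, list(subfamilies), counts)
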