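"""Tree utilities and phylogeny-anchored score-cutoff derivation.

The acceptance threshold for each subfamily model is anchored on a labeled
reference gene phylogeny: the *basalmost* members of the subfamily clade
(the earliest-diverging lineage, operationalized as the smaller child
subtree of the clade MRCA) give the inside anchor, the leaves of the
clade's sister group ("next closest clade") give the outside anchor, and
the cutoff is placed at the arithmetic midpoint of the two. If the inside
minimum does not exceed the outside maximum the intervals overlap and a
clade merge is recommended (the RAM1/RAD1 pattern).

Trees are handled through dendropy; this module is the package surface
for Newick reading/writing, outgroup rooting and MRCA queries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import dendropy

from symgras.errors import ArgumentError, DataError, FormatError

if TYPE_CHECKING:  # pragma: no cover
    from symgras.classify import ScoreTable

logger = logging.getLogger(__name__)

SUBFAMILIES = ("NSP1", "NSP2", "RAM1", "RAD1")


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_tree(path: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    """Read a Newick tree (quoted labels ok, bracket comments stripped)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse Newick ({exc})") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    elif not tree.is_rooted:
        tree.is_rooted = True  # treat the seed node as the root
    return tree


def parse_tree(newick: str, rooted: bool | None = None) -> dendropy.Tree:
    """Parse a Newick string."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick string ({exc})") from exc
    if rooted is not None:
        tree.is_rooted = rooted
    elif not tree.is_rooted:
        tree.is_rooted = True
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    )


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _leafset(node: dendropy.Node) -> set[str]:
    return {leaf.taxon.label for leaf in node.leaf_iter()}


# ---------------------------------------------------------------------------
# Clade definitions and cutoffs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CladeDefinition:
    """A named subfamily clade given by its member leaf ids."""

    subfamily: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ArgumentError(f"clade {self.subfamily!r} has no members")
        object.__setattr__(self, "member_ids", frozenset(self.member_ids))


@dataclass(frozen=True)
class CladeCutoff:
    """Per-subfamily acceptance threshold in bits.

    ``cutoff_bits`` lies weakly between ``in_clade_basal_min`` (minimum
    score of the basalmost clade members) and ``out_clade_max`` (maximum
    score of the sister clade); ``overlap_flag`` is raised exactly when
    the in-clade minimum does not exceed the out-clade maximum.
    """

    subfamily: str
    cutoff_bits: float
    in_clade_basal_min: float
    out_clade_max: float
    overlap_flag: bool
    merged_with: str | None = None

    @property
    def components(self) -> tuple[str, ...]:
        """Component subfamily model names (more than one for a merge)."""
        return tuple(self.subfamily.split("+"))


# ---------------------------------------------------------------------------
# Rooting and clade queries
# ---------------------------------------------------------------------------

def root_by_outgroup(tree: dendropy.Tree, outgroup_ids: Iterable[str]) -> dendropy.Tree:
    """Root a tree on the edge connecting the outgroup to the ingroup.

    The outgroup leaves must be separable by a single edge; the returned
    tree has the outgroup as one child of the root. The input tree is not
    modified.
    """
    outgroup = set(outgroup_ids)
    if not outgroup:
        raise ArgumentError("outgroup_ids is empty")
    t = tree.clone(depth=1)
    t.is_rooted = True
    labels = set(leaf_labels(t))
    missing = sorted(outgroup - labels)
    if missing:
        raise ArgumentError(f"outgroup ids absent from tree: {missing}")
    if outgroup == labels:
        raise ArgumentError("outgroup cannot contain every leaf")

    # orient from a non-outgroup leaf so the outgroup (if separable) forms
    # a subtree, then reroot at that subtree's stem edge
    anchor = next(l for l in t.leaf_node_iter() if l.taxon.label not in outgroup)
    t.reroot_at_edge(anchor.edge, update_bipartitions=False)
    t.suppress_unifurcations()
    if len(outgroup) == 1:
        node = next(l for l in t.leaf_node_iter() if l.taxon.label in outgroup)
    else:
        taxa = [t.taxon_namespace.get_taxon(x) for x in outgroup]
        node = t.mrca(taxa=taxa)
    spanned = _leafset(node)
    extra = sorted(spanned - outgroup)
    if extra:
        raise ArgumentError(
            "outgroup is not separable by a single edge; "
            f"conflicting leaves inside its span: {extra}"
        )
    t.reroot_at_edge(node.edge, update_bipartitions=False)
    t.suppress_unifurcations()
    t.is_rooted = True
    return t


def mrca(tree: dendropy.Tree, ids: Iterable[str]) -> dendropy.Node:
    """Most recent common ancestor of the given leaf ids (rooted tree)."""
    ids = list(ids)
    if not ids:
        raise ArgumentError("mrca of an empty id set is undefined")
    labels = set(leaf_labels(tree))
    missing = sorted(set(ids) - labels)
    if missing:
        raise ArgumentError(f"ids absent from tree: {missing}")
    if len(set(ids)) == 1:
        return next(l for l in tree.leaf_node_iter() if l.taxon.label == ids[0])
    tree.is_rooted = True
    taxa = [tree.taxon_namespace.get_taxon(x) for x in set(ids)]
    return tree.mrca(taxa=taxa)


def basalmost_members(tree: dendropy.Tree, clade: CladeDefinition) -> set[str]:
    """Leaf ids anchoring the inside edge of the cutoff interval.

    Returns the clade members in the child subtree of the clade MRCA
    containing the fewest members (the earliest-diverging lineage under
    this convention); ties return the union of the tied children. A
    non-monophyletic clade triggers a warning and proceeds on the
    intersection of the MRCA subtree with the member set.
    """
    members = set(clade.member_ids)
    node = mrca(tree, members)
    spanned = _leafset(node)
    if spanned != members:
        logger.warning(
            "clade %s is not monophyletic (%d interloper leaves); "
            "proceeding on MRCA-subtree members",
            clade.subfamily, len(spanned - members),
        )
    if node.is_leaf():
        return {node.taxon.label}
    per_child = [
        _leafset(c) & members for c in node.child_nodes()
    ]
    per_child = [s for s in per_child if s]
    smallest = min(len(s) for s in per_child)
    out: set[str] = set()
    for s in per_child:
        if len(s) == smallest:
            out |= s
    return out


def nearest_outside_clade(
    tree: dendropy.Tree,
    clade: CladeDefinition,
    exclude: Iterable[str] = (),
) -> set[str]:
    """Leaves of the sister group of the clade's MRCA.

    ``exclude`` removes outgroup leaves used for rooting from the result.
    Raises if the clade MRCA is the root (no sister group exists).
    """
    node = mrca(tree, clade.member_ids)
    parent = node.parent_node
    if parent is None:
        raise ArgumentError(
            f"clade {clade.subfamily!r} spans the root: no sister clade exists"
        )
    sisters: set[str] = set()
    for sib in parent.child_nodes():
        if sib is not node:
            sisters |= _leafset(sib)
    sisters -= set(exclude)
    if not sisters:
        raise ArgumentError(
            f"sister group of clade {clade.subfamily!r} contains only excluded leaves"
        )
    return sisters


def derive_cutoff(
    scores: "ScoreTable",
    tree: dendropy.Tree,
    clade: CladeDefinition,
    model_name: str | None = None,
    exclude: Iterable[str] = (),
) -> CladeCutoff:
    """Derive the clade's acceptance cutoff from anchored scores.

    The cutoff is the arithmetic midpoint between the minimum model score
    of the basalmost clade members and the maximum score of the nearest
    outside clade; the overlap flag is raised when those intervals cross.
    """
    model = model_name or clade.subfamily
    basal = sorted(basalmost_members(tree, clade))
    outside = sorted(nearest_outside_clade(tree, clade, exclude=exclude))
    components = model.split("+")

    def score_of(seq_id: str) -> float:
        return max(scores.get(seq_id, comp) for comp in components)

    missing = [
        sid for sid in basal + outside
        if any(not scores.has(sid, comp) for comp in components)
    ]
    if missing:
        raise DataError(
            f"missing {model} scores for cutoff anchors: {sorted(set(missing))}"
        )
    in_min = min(score_of(sid) for sid in basal)
    out_max = max(score_of(sid) for sid in outside)
    return CladeCutoff(
        subfamily=model,
        cutoff_bits=(in_min + out_max) / 2.0,
        in_clade_basal_min=in_min,
        out_clade_max=out_max,
        overlap_flag=in_min <= out_max,
    )


def merge_clades(a: CladeDefinition, b: CladeDefinition, order: Sequence[str] = SUBFAMILIES) -> CladeDefinition:
    """Union two clades into a merged ``A+B`` clade (configured name order)."""
    names = sorted(
        {a.subfamily, b.subfamily},
        key=lambda n: order.index(n) if n in order else len(order),
    )
    return CladeDefinition("+".join(names), a.member_ids | b.member_ids)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_clades_tsv(path: str | Path) -> list[CladeDefinition]:
    """Two-column TSV (subfamily, leaf id) -> clade definitions."""
    members: dict[str, set[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            fam, leaf = parts
            if fam == "subfamily" and leaf == "leaf_id":
                continue
            if fam not in members:
                members[fam] = set()
                order.append(fam)
            members[fam].add(leaf)
    if not members:
        raise FormatError(f"{path}: no clade definitions found")
    return [CladeDefinition(f, frozenset(members[f])) for f in order]


def write_clades_tsv(clades: Sequence[CladeDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("subfamily\tleaf_id\n")
        for clade in clades:
            for leaf in sorted(clade.member_ids):
                fh.write(f"{clade.subfamily}\t{leaf}\n")


def write_cutoffs_tsv(cutoffs: Sequence[CladeCutoff], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "subfamily\tcutoff_bits\tin_clade_basal_min\tout_clade_max\t"
            "overlap_flag\tmerged_with\n"
        )
        for c in cutoffs:
            fh.write(
                f"{c.subfamily}\t{c.cutoff_bits:.6f}\t{c.in_clade_basal_min:.6f}\t"
                f"{c.out_clade_max:.6f}\t{str(c.overlap_flag).lower()}\t"
                f"{c.merged_with or '-'}\n"
            )


def read_cutoffs_tsv(path: str | Path) -> list[CladeCutoff]:
    cutoffs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["subfamily", "cutoff_bits"]:
            raise FormatError(f"{path}: unexpected cutoff TSV header")
        for ln in fh:
            if not ln.strip():
                continue
            fam, cut, inmin, outmax, flag, merged = ln.rstrip("\n").split("\t")
            cutoffs.append(
                CladeCutoff(
                    subfamily=fam,
                    cutoff_bits=float(cut),
                    in_clade_basal_min=float(inmin),
                    out_clade_max=float(outmax),
                    overlap_flag=flag == "true",
                    merged_with=None if merged == "-" else merged,
                )
            )
    return cutoffs
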