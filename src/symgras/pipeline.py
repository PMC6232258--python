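"""End-to-end orchestration: proteomes + seeds + trees -> event report.

Stages: dedupe -> build subfamily HMMs -> score every candidate against
every model -> root the reference gene tree by the outgroup -> derive
clade cutoffs (merging clades whose score intervals overlap, the
RAM1/RAD1 pattern) -> classify -> copy-number matrix -> Dollo +
copy-number parsimony -> event report. Every intermediate is written as
TSV/FASTA/Newick together with a machine-readable manifest; outputs are
byte-identical across reruns of the same config and seed (no timestamps).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from symgras import __version__
from symgras import clade_tools, classify, evolution, profile_hmm, seqio
from symgras.clade_tools import CladeCutoff, CladeDefinition
from symgras.errors import ArgumentError, DataError, SymgrasError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Validated run configuration (YAML-backed, versioned schema)."""

    proteomes: dict[str, str]  # species code -> FASTA path
    seed_alignments: dict[str, str]  # subfamily -> aligned FASTA path
    gene_tree: str
    clades: str
    species_tree: str
    output_dir: str
    outgroup: list[str] = field(default_factory=list)
    extra_sequences: list[str] = field(default_factory=list)  # e.g. outgroup FASTA
    build_params: profile_hmm.BuildParams = field(default_factory=profile_hmm.BuildParams)
    ambiguity_margin: float = classify.DEFAULT_AMBIGUITY_MARGIN
    evidence: dict[str, str] = field(default_factory=dict)
    root_state: str = "present"
    transcriptome_absence_as_missing: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise DataError(f"{path}: config must be a mapping")
        version = raw.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise DataError(f"{path}: unsupported schema_version {version}")
        bp = raw.pop("build_params", {}) or {}
        config = cls(
            proteomes=dict(raw.pop("proteomes")),
            seed_alignments=dict(raw.pop("seed_alignments")),
            gene_tree=raw.pop("gene_tree"),
            clades=raw.pop("clades"),
            species_tree=raw.pop("species_tree"),
            output_dir=raw.pop("output_dir"),
            outgroup=list(raw.pop("outgroup", [])),
            extra_sequences=list(raw.pop("extra_sequences", [])),
            build_params=profile_hmm.BuildParams(**bp),
            ambiguity_margin=float(raw.pop("ambiguity_margin", classify.DEFAULT_AMBIGUITY_MARGIN)),
            evidence=dict(raw.pop("evidence", {}) or {}),
            root_state=raw.pop("root_state", "present"),
            transcriptome_absence_as_missing=bool(
                raw.pop("transcriptome_absence_as_missing", False)
            ),
            seed=int(raw.pop("seed", 0)),
        )
        if raw:
            raise DataError(f"{path}: unknown config keys {sorted(raw)}")
        base = path.parent
        config._resolve_paths(base)
        return config

    def _resolve_paths(self, base: Path) -> None:
        self.proteomes = {
            sp: str((base / p)) for sp, p in self.proteomes.items()
        }
        self.seed_alignments = {
            f: str(base / p) for f, p in self.seed_alignments.items()
        }
        self.gene_tree = str(base / self.gene_tree)
        self.clades = str(base / self.clades)
        self.species_tree = str(base / self.species_tree)
        self.extra_sequences = [str(base / p) for p in self.extra_sequences]
        if not Path(self.output_dir).is_absolute():
            self.output_dir = str(base / self.output_dir)

    def validate_paths(self) -> None:
        missing = []
        for p in (
            list(self.proteomes.values())
            + list(self.seed_alignments.values())
            + [self.gene_tree, self.clades, self.species_tree]
            + list(self.extra_sequences)
        ):
            if not Path(p).exists():
                missing.append(p)
        if missing:
            raise DataError(f"config references missing paths: {missing}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d


class StageError(SymgrasError):
    """An error occurring inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Any stage error aborts with a stage-named message; outputs written by
    earlier stages are retained and the manifest records the failed stage.
    """
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "symgras_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    stage = "init"

    def finish_stage(name: str, **counts) -> None:
        manifest["stages"][name] = {k: int(v) for k, v in counts.items()}
        logger.info("stage %s: %s", name, counts)

    try:
        stage = "read_sequences"
        candidates: list[seqio.ProteinSequence] = []
        for sp in sorted(config.proteomes):
            candidates.extend(seqio.read_fasta(config.proteomes[sp]))
        extra = []
        for p in config.extra_sequences:
            extra.extend(seqio.read_fasta(p))
        finish_stage(stage, candidates=len(candidates), extra=len(extra))

        stage = "dedupe"
        kept, removed_map = seqio.dedupe_identical(candidates)
        seqio.write_fasta(kept, out / "deduped.fasta")
        seqio.write_removed_map(removed_map, out / "removed_map.tsv")
        finish_stage(stage, kept=len(kept),
                     removed=sum(len(v) for v in removed_map.values()))

        stage = "build_hmms"
        models = []
        for fam in config.seed_alignments:
            msa = seqio.read_alignment(config.seed_alignments[fam])
            hmm = profile_hmm.build_profile_hmm(msa, config.build_params, fam)
            profile_hmm.write_hmm(hmm, out / "models" / f"{fam}.hmm")
            models.append(hmm)
        finish_stage(stage, models=len(models))

        stage = "score"
        to_score = kept + [s for s in extra if s.id not in {k.id for k in kept}]
        records = profile_hmm.score_sequences(models, to_score)
        scores = classify.ScoreTable.from_records(records)
        scores.to_tsv(out / "scores.tsv")
        finish_stage(stage, scores=len(scores))

        stage = "root_gene_tree"
        gene_tree = clade_tools.read_tree(config.gene_tree)
        if config.outgroup:
            gene_tree = clade_tools.root_by_outgroup(gene_tree, config.outgroup)
        clade_tools.write_tree(gene_tree, out / "rooted_gene_tree.nwk")
        finish_stage(stage, leaves=len(gene_tree.leaf_nodes()))

        stage = "derive_cutoffs"
        clades = clade_tools.read_clades_tsv(config.clades)
        cutoffs = derive_cutoffs_with_merging(
            scores, gene_tree, clades, exclude=config.outgroup
        )
        clade_tools.write_cutoffs_tsv(cutoffs, out / "cutoffs.tsv")
        finish_stage(stage, cutoffs=len(cutoffs),
                     merged=sum(1 for c in cutoffs if len(c.components) > 1))

        stage = "classify"
        # candidate sequences only: outgroup/rooting extras are not classified
        candidate_ids = {s.id for s in kept}
        table = classify.ScoreTable.from_records(
            [r for r in scores.records() if r.seq_id in candidate_ids]
        )
        assignments = classify.classify_sequences(
            table, cutoffs, config.ambiguity_margin
        )
        classify.write_assignments_tsv(assignments, out / "assignments.tsv")
        n_assigned = sum(1 for a in assignments if a.subfamily != classify.UNASSIGNED)
        finish_stage(stage, assignments=len(assignments), assigned=n_assigned)

        stage = "copy_matrix"
        species_tree = clade_tools.read_tree(config.species_tree)
        subfams = [c.subfamily for c in clades]
        matrix = evolution.build_copy_matrix(
            assignments, species_tree, config.evidence, removed_map,
            subfamilies=subfams,
        )
        matrix.to_tsv(out / "copy_matrix.tsv")
        matrix.evidence_to_tsv(out / "evidence.tsv")
        finish_stage(stage, species=len(matrix.species),
                     total_copies=int(matrix.counts.sum()))

        stage = "reconstruct"
        recon = evolution.reconstruct_events(
            matrix, species_tree,
            root_state=config.root_state,
            transcriptome_absence_as_missing=config.transcriptome_absence_as_missing,
        )
        report = evolution.event_report(recon, matrix)
        report.events_tsv(out / "events.tsv")
        (out / "report.txt").write_text(report.to_text())
        finish_stage(stage, events=len(recon.branch_events),
                     total_cost=recon.total_cost)
    except SymgrasError as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out


def derive_cutoffs_with_merging(
    scores: classify.ScoreTable,
    gene_tree,
    clades: Sequence[CladeDefinition],
    exclude: Sequence[str] = (),
    max_rounds: int = 3,
) -> list[CladeCutoff]:
    """Derive all cutoffs, merging clades whose score intervals overlap.

    When a clade's basal-minimum does not exceed its nearest-outside
    maximum, it is merged with the subfamily owning the plurality of its
    nearest-outside leaves and a joint cutoff is derived for the union
    clade (scored by the best of the component models), mirroring the
    joint treatment of largely overlapping member lists.
    """
    clade_by_name = {c.subfamily: c for c in clades}
    order = [c.subfamily for c in clades]
    for _ in range(max_rounds):
        cutoffs = {
            name: clade_tools.derive_cutoff(
                scores, gene_tree, clade_by_name[name], exclude=exclude
            )
            for name in clade_by_name
        }
        overlapped = [n for n, c in cutoffs.items() if c.overlap_flag]
        if not overlapped:
            return [cutoffs[n] for n in clade_by_name]
        name = overlapped[0]
        clade = clade_by_name[name]
        outside = clade_tools.nearest_outside_clade(gene_tree, clade, exclude=exclude)
        partner = None
        best_overlap = 0
        for other, oc in clade_by_name.items():
            if other == name:
                continue
            n = len(outside & oc.member_ids)
            if n > best_overlap:
                best_overlap, partner = n, other
        if partner is None:
            logger.warning(
                "cutoff for %s overlaps but no partner clade found; keeping flag",
                name,
            )
            return [cutoffs[n] for n in clade_by_name]
        logger.info("merging overlapping clades %s and %s", name, partner)
        merged = clade_tools.merge_clades(
            clade_by_name.pop(name), clade_by_name.pop(partner), order=order
        )
        clade_by_name[merged.subfamily] = merged
    cutoffs = {
        name: clade_tools.derive_cutoff(
            scores, gene_tree, clade_by_name[name], exclude=exclude
        )
        for name in clade_by_name
    }
    return list(cutoffs.values())


def write_pipeline_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_for_synthetic_dataset(
    dataset_dir: str | Path,
    output_dir: str = "run",
    seed: int = 0,
    **overrides,
) -> PipelineConfig:
    """Pipeline config pointing at a :meth:`SyntheticDataset.write` directory."""
    dataset_dir = Path(dataset_dir)
    with open(dataset_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    files = manifest["files"]
    proteomes = {
        key.split(":", 1)[1]: str(dataset_dir / rel)
        for key, rel in files.items()
        if key.startswith("proteome:")
    }
    seeds = {
        key.split(":", 1)[1]: str(dataset_dir / rel)
        for key, rel in files.items()
        if key.startswith("seed:")
    }
    from symgras.synthetic_data import OUTGROUP_IDS

    kwargs = dict(
        proteomes=proteomes,
        seed_alignments=seeds,
        gene_tree=str(dataset_dir / files["gene_tree"]),
        clades=str(dataset_dir / files["clades"]),
        species_tree=str(dataset_dir / files["species_tree"]),
        extra_sequences=[str(dataset_dir / files["outgroup"])],
        outgroup=list(OUTGROUP_IDS),
        output_dir=str(output_dir),
        seed=seed,
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)
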