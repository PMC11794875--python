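"""End-to-end orchestration: screen -> phylo -> context from one config.

A run is fully described by a :class:`RunConfig` (loadable from YAML).
Every stage writes its intermediate artifact into the output directory, and
the final report records per-stage counts, all thresholds applied, the seed
and the package version, so identical configurations reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, context, phylo, screen
from .errors import AzescanError, DataError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and thresholds for a full anchor-context analysis run."""

    proteins_fasta: str  # homolog protein sequences (headers may carry contig_len=)
    features_path: str  # GFF3 or flat TSV of CDS features
    out_dir: str
    hits_path: str | None = None  # BLAST tabular; when absent, all proteins pass
    neighborhood_fasta: str | None = None  # window protein seqs; default: proteins_fasta
    msa_path: str | None = None  # precomputed alignment of representatives
    tree_path: str | None = None  # externally computed newick; skips NJ

    min_identity: float = screen.DEFAULT_MIN_IDENTITY
    min_coverage: float = screen.DEFAULT_MIN_COVERAGE
    max_evalue: float = screen.DEFAULT_MAX_EVALUE
    derep_identity: float = screen.DEFAULT_DEREP_IDENTITY
    trim_gap_fraction: float = phylo.DEFAULT_MAX_GAP_FRACTION
    bootstrap_replicates: int = phylo.DEFAULT_BOOTSTRAP_REPLICATES
    flank: int = context.DEFAULT_FLANK
    inflation: float = context.DEFAULT_INFLATION
    relevance_threshold: float = context.DEFAULT_RELEVANCE_THRESHOLD
    max_gap: int = context.DEFAULT_MAX_GAP
    min_conservation: float = context.DEFAULT_MIN_CONSERVATION
    patience: int = context.DEFAULT_PATIENCE
    distance_mode: str = "all_occurrences"
    seed: int = 0
    anchor_ids: list[str] = field(default_factory=list)
    contig_lengths: dict[str, int] = field(default_factory=dict)
    skip_phylo: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("proteins_fasta", "features_path", "hits_path",
                     "neighborhood_fasta", "msa_path", "tree_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ParameterError(f"config error: {name} path does not exist: {p}")


def _read_protein_fasta(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    contig_lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        for token in rec.description.split():
            if token.startswith("contig_len="):
                contig_lengths[rec.id] = int(token.split("=", 1)[1])
    if not seqs:
        raise DataError(f"no sequences in {path}")
    return seqs, contig_lengths


def run_all(config: RunConfig) -> dict:
    """Execute screen -> phylo -> context and return the run report dict.

    Any stage error aborts with the stage name; artifacts written so far
    stay on disk and are listed in the raised error's message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("contig_lengths", "anchor_ids")
        },
        "stages": {},
        "artifacts": [],
    }
    written: list[str] = []

    def _stage(name: str):
        logger.info("stage %s starting", name)
        return name

    try:
        stage = _stage("screen")
        seqs, header_contig_lengths = _read_protein_fasta(config.proteins_fasta)
        contig_lengths = {**header_contig_lengths, **config.contig_lengths}

        retained_ids = set(seqs)
        n_hits = n_retained = 0
        if config.hits_path:
            hits = screen.read_blast_tab(config.hits_path)
            n_hits = len(hits)
            kept = screen.filter_hits(
                hits, config.min_identity, config.min_coverage, config.max_evalue
            )
            n_retained = len(kept)
            retained_ids = {h.subject_id for h in kept} & set(seqs)
        records = [
            screen.SeqRecord(id=i, seq=seqs[i], contig_length=contig_lengths.get(i, 0))
            for i in sorted(retained_ids)
        ]
        clusters = screen.greedy_cluster(records, config.derep_identity)
        clusters = screen.assign_representatives(clusters, records)
        cluster_path = out / "clusters.tsv"
        screen.write_cluster_table(clusters, cluster_path)
        written.append(str(cluster_path))
        reps = [c.representative for c in clusters.clusters]
        report["stages"]["screen"] = {
            "hits_in": n_hits,
            "hits_retained": n_retained,
            "proteins": len(records),
            "clusters": len(clusters),
        }

        stage = _stage("phylo")
        if not config.skip_phylo and len(reps) >= 3:
            if config.tree_path:
                newick = Path(config.tree_path).read_text().strip()
                report["stages"]["phylo"] = {"source": "external", "leaves": None}
            else:
                if config.msa_path:
                    aln = phylo.read_fasta_alignment(config.msa_path)
                else:
                    aln = phylo.align_sequences({r: seqs[r] for r in reps})
                aln = phylo.trim_alignment(aln, config.trim_gap_fraction)
                tree = phylo.bootstrap_support(
                    aln, config.bootstrap_replicates, seed=config.seed
                )
                newick = tree.to_newick(with_support=True)
                report["stages"]["phylo"] = {
                    "source": "internal_nj",
                    "leaves": len(aln.ids),
                    "alignment_columns": aln.n_cols,
                    "bootstrap_replicates": config.bootstrap_replicates,
                }
            tree_path = out / "representatives.nwk"
            tree_path.write_text(newick + "\n")
            written.append(str(tree_path))
        else:
            report["stages"]["phylo"] = {"source": "skipped", "leaves": len(reps)}

        stage = _stage("context")
        if config.features_path.endswith((".gff", ".gff3")):
            features = context.read_features_gff3(config.features_path)
        else:
            features = context.read_features_tsv(config.features_path)
        anchors = config.anchor_ids or reps
        feature_ids = {f.protein_id for f in features}
        windows = []
        feature_contig_lengths = {
            f.contig_id: config.contig_lengths.get(f.contig_id)
            for f in features
        }
        for anchor in anchors:
            if anchor not in feature_ids:
                continue
            contig = next(f.contig_id for f in features if f.protein_id == anchor)
            windows.append(
                context.extract_window(
                    features, anchor, config.flank,
                    contig_length=feature_contig_lengths.get(contig),
                )
            )
        if not windows:
            raise DataError("no anchor windows could be extracted")

        neighborhood_seqs = seqs
        if config.neighborhood_fasta:
            neighborhood_seqs, _ = _read_protein_fasta(config.neighborhood_fasta)
        window_proteins = {
            gid: neighborhood_seqs[gid]
            for w in windows
            for gid in w.gene_ids
            if gid in neighborhood_seqs
        }
        graph = context.build_similarity_graph(window_proteins)
        families = context.mcl_cluster(graph, config.inflation)
        table = context.relevance_scores(windows, families, config.distance_mode)
        table = context.annotate_relevant(table, config.relevance_threshold)

        family_path = out / "families.tsv"
        table.to_dataframe().to_csv(family_path, sep="\t", index=False)
        written.append(str(family_path))

        regions = [
            context.delineate_region(
                w, table, config.max_gap, config.min_conservation, config.patience
            )
            for w in windows
        ]
        region_path = out / "regions.tsv"
        with open(region_path, "w") as fh:
            fh.write("contig\tanchor\tregion_start\tregion_end\tgenes\n")
            for r in regions:
                fh.write(
                    f"{r.anchor.contig_id}\t{r.anchor.protein_id}\t{r.span[0]}"
                    f"\t{r.span[1]}\t{','.join(r.gene_ids)}\n"
                )
        written.append(str(region_path))

        map_path = out / "neighborhood_map.json"
        with open(map_path, "w") as fh:
            json.dump(context.neighborhood_map_json(windows, table), fh, indent=1,
                      sort_keys=True)
        written.append(str(map_path))

        report["stages"]["context"] = {
            "windows": len(windows),
            "neighborhood_proteins": len(window_proteins),
            "families": len(table.families),
            "marked_families": len(table.marked_families()),
        }
    except AzescanError as exc:
        raise type(exc)(
            f"stage {stage!r} failed: {exc}; artifacts written: {written}"
        ) from exc

    report["artifacts"] = written
    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
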