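"""Genomic-context conservation analysis around anchor genes.

Given annotated contigs each carrying one homologue of the anchor protein
(an AZE synthase), this module

1. extracts the neighborhood window spanning 20 kb upstream of the anchor's
   start codon to 20 kb downstream of its stop codon (clipped at contig
   ends),
2. clusters the neighborhood proteins into families by Markov clustering
   (MCL, inflation 1.3) of an all-vs-all protein similarity graph,
3. assigns each family a relevance score: the number of windows in which
   the family occurs divided by the median CDS-rank distance of its members
   to the anchor, marking families with score >= 2 as context-relevant, and
4. delineates a compact conserved sub-region around the anchor from family
   conservation and intergenic gaps.

Distances are counted in CDS rank (ordinal position along the contig,
strand-ignorant); base-pair spans are carried alongside but do not enter
the score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .align import global_alignment_score, self_score
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 20_000  # bases either side of the anchor CDS
DEFAULT_INFLATION = 1.3
DEFAULT_RELEVANCE_THRESHOLD = 2.0
DEFAULT_MAX_GAP = 500  # bases
DEFAULT_MIN_CONSERVATION = 0.25  # fraction of windows
DEFAULT_PATIENCE = 2  # consecutive unsupported genes tolerated

EVALUE_WEIGHT_CAP = 200.0
INTERNAL_EDGE_CUTOFF = 0.2
MCL_PRUNE = 1e-5
MCL_CONVERGENCE = 1e-6
MCL_MAX_ITER = 200


@dataclass(frozen=True)
class GeneFeature:
    """One CDS on a contig (1-based, inclusive coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ParameterError(
                f"feature {self.protein_id}: need 1 <= start <= end, "
                f"got [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ParameterError(f"feature {self.protein_id}: strand must be '+' or '-'")


@dataclass
class WindowGene:
    feature: GeneFeature
    cds_distance: int  # |rank - anchor rank|
    signed_offset: int  # rank - anchor rank
    intergenic_gap: int  # bases to the previous gene in the window (first gene: 0)


@dataclass
class NeighborhoodWindow:
    anchor: GeneFeature
    genes: list[WindowGene]  # ordered by start coordinate; includes the anchor
    span: tuple[int, int]  # window interval on the contig, 1-based inclusive

    @property
    def gene_ids(self) -> list[str]:
        return [g.feature.protein_id for g in self.genes]


def read_features_gff3(path: str | Path) -> list[GeneFeature]:
    """CDS features from a GFF3 file, via gffutils (in-memory db).

    The protein id is taken from the ID attribute (falling back to
    protein_id, then Name).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats: list[GeneFeature] = []
    for f in db.features_of_type("CDS", order_by=("seqid", "start")):
        pid = (f.attributes.get("ID") or f.attributes.get("protein_id")
               or f.attributes.get("Name") or [f.id])[0]
        feats.append(
            GeneFeature(contig_id=f.seqid, start=f.start, end=f.end,
                        strand=f.strand, protein_id=pid)
        )
    if not feats:
        raise DataError(f"no CDS features in {path}")
    return feats


def read_features_tsv(path: str | Path) -> list[GeneFeature]:
    """Flat feature table: contig_id, start, end, strand, protein_id (with header)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"contig_id", "start", "end", "strand", "protein_id"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"feature table missing columns: {sorted(missing)}")
    return [
        GeneFeature(contig_id=str(r.contig_id), start=int(r.start), end=int(r.end),
                    strand=str(r.strand), protein_id=str(r.protein_id))
        for r in df.itertuples()
    ]


def _ranked_contig(features: list[GeneFeature], contig: str) -> list[GeneFeature]:
    sub = [f for f in features if f.contig_id == contig]
    return sorted(sub, key=lambda f: (f.start, f.end, f.protein_id))


def extract_window(
    features: list[GeneFeature],
    anchor_id: str,
    flank: int = DEFAULT_FLANK,
    contig_length: int | None = None,
) -> NeighborhoodWindow:
    """Anchor-centered window of CDS features within ``flank`` bases.

    Includes every CDS overlapping [anchor.start - flank, anchor.end +
    flank], clipped at position 1 and at the contig end when the contig is
    shorter than the full window.  CDS-rank distances and intergenic gaps
    are populated for every retained gene.
    """
    if flank <= 0:
        raise ParameterError("flank must be positive (bases)")
    anchors = [f for f in features if f.protein_id == anchor_id]
    if not anchors:
        raise DataError(f"anchor id {anchor_id!r} not found among features")
    anchor = anchors[0]
    ranked = _ranked_contig(features, anchor.contig_id)
    anchor_rank = next(i for i, f in enumerate(ranked) if f.protein_id == anchor_id)

    lo = max(1, anchor.start - flank)
    hi = anchor.end + flank
    if contig_length is not None:
        hi = min(hi, contig_length)

    genes: list[WindowGene] = []
    prev_end: int | None = None
    for rank, f in enumerate(ranked):
        if f.end < lo or f.start > hi:
            continue
        gap = 0 if prev_end is None else max(0, f.start - prev_end - 1)
        genes.append(
            WindowGene(
                feature=f,
                cds_distance=abs(rank - anchor_rank),
                signed_offset=rank - anchor_rank,
                intergenic_gap=gap,
            )
        )
        prev_end = f.end
    return NeighborhoodWindow(anchor=anchor, genes=genes, span=(lo, hi))


def build_similarity_graph(
    proteins: dict[str, str],
    external_hits: list | None = None,
) -> nx.Graph:
    """All-vs-all protein similarity graph for family clustering.

    With ``external_hits`` (HitRecord-like objects with query_id,
    subject_id, e_value), the edge weight is -log10(E-value) capped at
    200, symmetrized by maximum.  Without, weights are global alignment
    scores normalized by the smaller self-score, keeping edges with
    normalized score >= 0.2.  No self-edges.
    """
    if len(proteins) < 2:
        raise ParameterError("need at least 2 proteins")
    g = nx.Graph()
    g.add_nodes_from(sorted(proteins))
    if external_hits is not None:
        for h in external_hits:
            if h.query_id not in proteins or h.subject_id not in proteins:
                raise DataError(
                    f"hit references unknown id: {h.query_id} vs {h.subject_id}"
                )
            if h.query_id == h.subject_id:
                continue
            w = EVALUE_WEIGHT_CAP if h.e_value <= 0 else min(
                -np.log10(h.e_value), EVALUE_WEIGHT_CAP
            )
            if w <= 0:
                continue
            u, v = h.query_id, h.subject_id
            if g.has_edge(u, v):
                g[u][v]["weight"] = max(g[u][v]["weight"], w)
            else:
                g.add_edge(u, v, weight=w)
        return g
    ids = sorted(proteins)
    selfs = {i: self_score(proteins[i]) for i in ids}
    for a_idx, u in enumerate(ids):
        for v in ids[a_idx + 1 :]:
            norm = global_alignment_score(proteins[u], proteins[v]) / min(
                selfs[u], selfs[v]
            )
            if norm >= INTERNAL_EDGE_CUTOFF:
                g.add_edge(u, v, weight=norm)
    return g


def mcl_cluster(graph: nx.Graph, inflation: float = DEFAULT_INFLATION) -> dict[str, str]:
    """Markov clustering of a similarity graph into protein families.

    Adds self-loops (weight = max incident edge weight; 1 for isolated
    nodes), column-normalizes, then alternates expansion (matrix square)
    and inflation (elementwise power + renormalization) with pruning of
    entries below 1e-5, stopping when the largest entry change falls below
    1e-6 or after 200 iterations (non-convergence logs a warning and the
    current clustering is returned).  Clusters are read off attractor rows;
    a node attracted to several clusters joins the one with the largest
    attraction, ties to the smallest cluster index.  Returns a gene ->
    family-id map with families labelled ``fam0000`` in order of their
    smallest node.
    """
    if inflation <= 1.0:
        raise ParameterError("inflation must exceed 1")
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if not np.isfinite(w) or w < 0:
            raise DataError(f"edge ({u}, {v}) has invalid weight {w}")
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = w
    loop = m.max(axis=0)
    loop[loop <= 0] = 1.0
    m[np.diag_indices(n)] = loop
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(MCL_MAX_ITER):
        prev = m
        m = m @ m  # expansion
        m = np.power(m, inflation)  # inflation
        m[m < MCL_PRUNE] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < MCL_CONVERGENCE:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within 200 iterations; using current state",
                      stacklevel=2)
        logger.warning("MCL non-convergence at %d iterations", MCL_MAX_ITER)

    # attractors carry mass on their own diagonal entry
    attractors = [i for i in range(n) if m[i, i] > 0]
    if not attractors:  # fully degenerate; every node its own family
        attractors = list(range(n))
    # group attractors that support each other into one cluster
    parent = list(range(len(attractors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pos = {a: k for k, a in enumerate(attractors)}
    for k, a in enumerate(attractors):
        for b in attractors[k + 1 :]:
            if m[a, b] > 0 or m[b, a] > 0:
                ra, rb = find(pos[a]), find(pos[b])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    cluster_of_attractor = {a: find(pos[a]) for a in attractors}
    cluster_ids = sorted(set(cluster_of_attractor.values()))
    renum = {c: i for i, c in enumerate(cluster_ids)}

    assignment: dict[int, int] = {}
    for j in range(n):
        attraction: dict[int, float] = {}
        for a in attractors:
            if m[a, j] > 0:
                c = renum[cluster_of_attractor[a]]
                attraction[c] = attraction.get(c, 0.0) + m[a, j]
        if not attraction:
            assignment[j] = -1  # orphan; becomes a singleton family below
            continue
        best = max(attraction.values())
        assignment[j] = min(c for c, v in attraction.items() if v >= best - 1e-12)

    # stable family labels ordered by each cluster's smallest node name
    groups: dict[int, list[str]] = {}
    orphan_key = max(assignment.values(), default=0) + 1
    for j, c in assignment.items():
        key = c if c >= 0 else orphan_key + j
        groups.setdefault(key, []).append(nodes[j])
    ordered = sorted(groups.values(), key=lambda g: min(g))
    fam_map: dict[str, str] = {}
    for i, members in enumerate(ordered):
        for v in members:
            fam_map[v] = f"fam{i:04d}"
    return fam_map


@dataclass
class FamilyStats:
    family_id: str
    occurrence_count: int  # windows containing >= 1 member
    member_count: int  # total member genes across windows
    median_distance: float  # CDS ranks
    relevance: float  # occurrence_count / median_distance (inf for the anchor family)
    is_anchor: bool
    marked: bool = False


@dataclass
class FamilyTable:
    gene_to_family: dict[str, str]
    families: list[FamilyStats]
    n_windows: int
    threshold: float | None = None

    def stats(self, family_id: str) -> FamilyStats:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    def marked_families(self) -> set[str]:
        return {f.family_id for f in self.families if f.marked}

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "family": f.family_id,
                    "occurrences": f.occurrence_count,
                    "members": f.member_count,
                    "median_cds_distance": f.median_distance,
                    "relevance": f.relevance,
                    "anchor_family": f.is_anchor,
                    "marked": f.marked,
                }
                for f in self.families
            ]
        )


def relevance_scores(
    windows: list[NeighborhoodWindow],
    families: dict[str, str],
    distance_mode: str = "all_occurrences",
) -> FamilyTable:
    """Score each family by occurrence count over median anchor distance.

    ``n_f`` counts windows containing at least one member (not the members
    themselves); the median distance is over all member occurrences across
    windows (``distance_mode="all_occurrences"``, default) or over each
    window's nearest member (``"per_window_min"``).  The anchor's own
    family has median distance 0: it is flagged, its score reported as
    infinity, and it is excluded from threshold marking.
    """
    if distance_mode not in ("all_occurrences", "per_window_min"):
        raise ParameterError(f"unknown distance_mode {distance_mode!r}")
    fam_windows: dict[str, set[int]] = {}
    fam_distances: dict[str, list[int]] = {}
    fam_members: dict[str, int] = {}
    anchor_families: set[str] = set()
    for w_idx, w in enumerate(windows):
        anchor_seen = False
        per_window_min: dict[str, int] = {}
        for g in w.genes:
            gid = g.feature.protein_id
            fam = families.get(gid)
            if fam is None:
                raise DataError(f"gene {gid} has no family assignment")
            if gid == w.anchor.protein_id:
                anchor_seen = True
                anchor_families.add(fam)
            fam_windows.setdefault(fam, set()).add(w_idx)
            fam_members[fam] = fam_members.get(fam, 0) + 1
            if distance_mode == "all_occurrences":
                fam_distances.setdefault(fam, []).append(g.cds_distance)
            else:
                cur = per_window_min.get(fam)
                if cur is None or g.cds_distance < cur:
                    per_window_min[fam] = g.cds_distance
        if distance_mode == "per_window_min":
            for fam, dist in per_window_min.items():
                fam_distances.setdefault(fam, []).append(dist)
        if not anchor_seen:
            raise DataError(
                f"window on {w.anchor.contig_id} does not contain its anchor"
            )
    stats: list[FamilyStats] = []
    for fam in sorted(fam_windows):
        n_f = len(fam_windows[fam])
        d_f = float(np.median(fam_distances[fam]))
        is_anchor = fam in anchor_families
        relevance = float("inf") if d_f == 0 else n_f / d_f
        stats.append(
            FamilyStats(
                family_id=fam,
                occurrence_count=n_f,
                member_count=fam_members[fam],
                median_distance=d_f,
                relevance=relevance,
                is_anchor=is_anchor,
            )
        )
    return FamilyTable(gene_to_family=dict(families), families=stats,
                       n_windows=len(windows))


def annotate_relevant(
    table: FamilyTable, threshold: float = DEFAULT_RELEVANCE_THRESHOLD
) -> FamilyTable:
    """Mark families with relevance >= ``threshold`` (inclusive).

    The anchor family is always marked; other families with an infinite
    score (median distance 0 without being the anchor family cannot occur)
    follow the threshold rule.
    """
    if threshold <= 0:
        raise ParameterError("relevance threshold must be positive")
    for f in table.families:
        f.marked = f.is_anchor or (
            not f.is_anchor and f.relevance >= threshold
        )
    table.threshold = threshold
    return table


def delineate_region(
    window: NeighborhoodWindow,
    table: FamilyTable,
    max_gap: int = DEFAULT_MAX_GAP,
    min_conservation: float = DEFAULT_MIN_CONSERVATION,
    patience: int = DEFAULT_PATIENCE,
) -> NeighborhoodWindow:
    """Narrow a window to the compact conserved region around its anchor.

    Growing outward from the anchor in both directions, a gene is
    "supported" when its family occurs in at least ``min_conservation`` of
    all windows OR its intergenic gap to the previously retained gene is at
    most ``max_gap`` bases.  Extension in a direction stops after
    ``patience`` consecutive unsupported genes, which are excluded; interior
    unsupported genes (followed by a supported one within patience) are
    retained.  The anchor is always retained.
    """
    if patience < 0:
        raise ParameterError("patience must be >= 0")
    genes = window.genes
    anchor_pos = next(
        i for i, g in enumerate(genes)
        if g.feature.protein_id == window.anchor.protein_id
    )

    def supported(i: int, prev_retained: int) -> bool:
        g = genes[i]
        fam = table.gene_to_family[g.feature.protein_id]
        frac = table.stats(fam).occurrence_count / table.n_windows
        if frac >= min_conservation:
            return True
        a, b = sorted((i, prev_retained))
        gap = max(0, genes[b].feature.start - genes[a].feature.end - 1)
        return gap <= max_gap

    keep = {anchor_pos}
    for step in (1, -1):
        unsupported_run = 0
        pending: list[int] = []
        prev_retained = anchor_pos
        i = anchor_pos + step
        while 0 <= i < len(genes):
            if supported(i, prev_retained):
                keep.update(pending)
                pending = []
                keep.add(i)
                prev_retained = i
                unsupported_run = 0
            else:
                unsupported_run += 1
                if unsupported_run > patience:
                    break
                pending.append(i)
            i += step

    retained = [g for i, g in enumerate(genes) if i in keep]
    lo = min(g.feature.start for g in retained)
    hi = max(g.feature.end for g in retained)
    return NeighborhoodWindow(anchor=window.anchor, genes=retained, span=(lo, hi))


def neighborhood_map_json(
    windows: list[NeighborhoodWindow], table: FamilyTable
) -> list[dict]:
    """Machine-readable neighborhood map (per window, per gene) for plotting."""
    out = []
    for w in windows:
        out.append(
            {
                "contig": w.anchor.contig_id,
                "anchor": w.anchor.protein_id,
                "genes": [
                    {
                        "protein_id": g.feature.protein_id,
                        "family": table.gene_to_family[g.feature.protein_id],
                        "offset": g.signed_offset,
                        "strand": g.feature.strand,
                        "marked": table.gene_to_family[g.feature.protein_id]
                        in table.marked_families(),
                    }
                    for g in w.genes
                ],
            }
        )
    return out
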