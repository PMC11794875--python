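"""Homolog-hit filtering and greedy identity dereplication.

The screening stage turns a BLASTp tabular hit list for the anchor proteins
(the AZE synthases AzeJ/VioH) into a non-redundant set of homologues:

1. :func:`filter_hits` keeps hits with identity >= 27%, coverage >= 60% on
   *both* query and subject, and E-value <= 1e-5 (all inclusive), collapsing
   duplicate subjects to their best E-value.
2. :func:`greedy_cluster` dereplicates the retained proteins by greedy
   incremental clustering at 95% identity: sequences are visited longest
   first, each joining the first existing cluster whose seed it matches at
   or above the threshold, otherwise seeding a new cluster.  Identity is
   exact matches of a global alignment divided by the shorter length (the
   convention of CD-HIT-style dereplication).
3. :func:`pick_representative` selects each cluster's representative as the
   member encoded on the longest contig (ties: longer protein, then
   lexicographically smallest id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .align import pairwise_identity
from .errors import ParameterError, ParseError

DEFAULT_MIN_IDENTITY = 27.0  # percent
DEFAULT_MIN_COVERAGE = 0.60  # fraction, applies to query AND subject
DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_DEREP_IDENTITY = 0.95


@dataclass(frozen=True)
class HitRecord:
    """One row of a homology search table."""

    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    e_value: float
    bitscore: float
    subject_length: int = 0
    subject_contig_length: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ParameterError("percent identity must be in [0, 100]")
        if not 0.0 <= self.query_coverage <= 1.0 or not 0.0 <= self.subject_coverage <= 1.0:
            raise ParameterError("coverages must be fractions in [0, 1]")
        if self.e_value < 0:
            raise ParameterError("E-value must be nonnegative")


@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence plus the length of the contig encoding it."""

    id: str
    seq: str
    contig_length: int = 0


@dataclass
class Cluster:
    representative: str
    members: list[str]
    identity_to_representative: dict[str, float] = field(default_factory=dict)


@dataclass
class ClusterSet:
    clusters: list[Cluster]

    def __len__(self) -> int:
        return len(self.clusters)

    def member_to_cluster(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for i, c in enumerate(self.clusters):
            for m in c.members:
                out[m] = i
        return out


def read_blast_tab(
    path: str | Path,
    query_lengths: dict[str, int] | None = None,
    subject_lengths: dict[str, int] | None = None,
) -> list[HitRecord]:
    """Read BLAST tabular output (``-outfmt 6``-style, tab-separated).

    Accepts the 12 default columns, optionally followed by qlen and slen
    (columns 13-14) and a subject contig length (column 15).  Coverages are
    computed as alignment span over the respective full length; when the
    qlen/slen columns are absent the lengths must come from the
    ``query_lengths``/``subject_lengths`` maps.  Comment lines starting with
    ``#`` and blank lines are ignored.  A malformed row raises
    :class:`ParseError` naming the 1-based line number.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"line {lineno}: expected >= 12 tab-separated columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
                if len(fields) >= 14:
                    qlen, slen = int(fields[12]), int(fields[13])
                else:
                    qlen = (query_lengths or {}).get(fields[0], 0)
                    slen = (subject_lengths or {}).get(fields[1], 0)
                contig_len = int(fields[14]) if len(fields) > 14 and fields[14] else None
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric field ({exc})") from exc
            if qlen <= 0 or slen <= 0:
                raise ParseError(
                    f"line {lineno}: sequence lengths unavailable (append qlen/slen "
                    "columns or pass length maps); cannot compute coverage"
                )
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=pident,
                    query_coverage=(abs(qend - qstart) + 1) / qlen,
                    subject_coverage=(abs(send - sstart) + 1) / slen,
                    e_value=evalue,
                    bitscore=bitscore,
                    subject_length=slen,
                    subject_contig_length=contig_len,
                )
            )
    return hits


def filter_hits(
    hits: list[HitRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[HitRecord]:
    """Apply the screening thresholds (all inclusive) and deduplicate subjects.

    A hit is retained when identity >= ``min_identity`` (percent), both the
    query and subject coverages are >= ``min_coverage`` (fractions), and
    E-value <= ``max_evalue``.  Among retained hits sharing a subject id,
    only the one with the best (smallest) E-value survives, earliest first
    on ties; output preserves input order of the survivors.
    """
    for name, v in (("min_identity", min_identity), ("min_coverage", min_coverage),
                    ("max_evalue", max_evalue)):
        if v is None or not float("-inf") < float(v) < float("inf"):
            raise ParameterError(f"{name} must be finite")
    passing = [
        (i, h)
        for i, h in enumerate(hits)
        if h.percent_identity >= min_identity
        and h.query_coverage >= min_coverage
        and h.subject_coverage >= min_coverage
        and h.e_value <= max_evalue
    ]
    best: dict[str, tuple[int, HitRecord]] = {}
    for i, h in passing:
        cur = best.get(h.subject_id)
        if cur is None or h.e_value < cur[1].e_value:
            best[h.subject_id] = (i, h)
    return [h for _, h in sorted(best.values(), key=lambda t: t[0])]


def greedy_cluster(
    records: list[SeqRecord], identity_threshold: float = DEFAULT_DEREP_IDENTITY
) -> ClusterSet:
    """Greedy incremental dereplication at an identity cutoff.

    Records are sorted by decreasing sequence length (ties keep input
    order).  The first seeds cluster 1; each subsequent record joins the
    FIRST existing cluster whose seed it matches at identity >=
    ``identity_threshold`` (global alignment, matches over shorter length),
    else it seeds a new cluster.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ParameterError("identity threshold must be in (0, 1]")
    if not records:
        raise ParameterError("no records to cluster")
    ordered = sorted(range(len(records)), key=lambda i: (-len(records[i].seq), i))
    clusters: list[Cluster] = []
    seeds: list[SeqRecord] = []
    for i in ordered:
        rec = records[i]
        placed = False
        for cluster, seed in zip(clusters, seeds):
            ident = pairwise_identity(rec.seq, seed.seq)
            if ident >= identity_threshold:
                cluster.members.append(rec.id)
                cluster.identity_to_representative[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative=rec.id, members=[rec.id],
                        identity_to_representative={rec.id: 1.0})
            )
            seeds.append(rec)
    return ClusterSet(clusters=clusters)


def pick_representative(
    members: list[str],
    contig_lengths: dict[str, int],
    protein_lengths: dict[str, int] | None = None,
) -> str:
    """Member encoded by the longest contig (missing length counts as 0).

    Ties fall to the longer protein, then to the lexicographically smallest
    id, so selection is total and deterministic.
    """
    if not members:
        raise ParameterError("empty cluster")
    protein_lengths = protein_lengths or {}
    return min(
        members,
        key=lambda m: (-contig_lengths.get(m, 0), -protein_lengths.get(m, 0), m),
    )


def assign_representatives(
    clusters: ClusterSet, records: list[SeqRecord]
) -> ClusterSet:
    """Re-pick every cluster representative by the longest-contig rule."""
    contig = {r.id: r.contig_length for r in records}
    protein = {r.id: len(r.seq) for r in records}
    new = []
    for c in clusters.clusters:
        rep = pick_representative(c.members, contig, protein)
        new.append(replace_representative(c, rep))
    return ClusterSet(clusters=new)


def replace_representative(cluster: Cluster, rep: str) -> Cluster:
    return Cluster(
        representative=rep,
        members=list(cluster.members),
        identity_to_representative=dict(cluster.identity_to_representative),
    )


def write_cluster_table(clusters: ClusterSet, path: str | Path) -> None:
    """TSV of (representative, member, identity-to-representative)."""
    with open(path, "w") as fh:
        fh.write("representative\tmember\tidentity\n")
        for c in clusters.clusters:
            for m in c.members:
                ident = c.identity_to_representative.get(m, float("nan"))
                fh.write(f"{c.representative}\t{m}\t{ident:.4f}\n")
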