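"""Synthetic fixtures: homolog sets and annotated contigs with planted families.

Every downstream stage of the anchor-gene context analysis is testable
without downloads because this module builds inputs with machine-readable
ground truth:

* :func:`gen_homolog_set` emits protein groups at a controlled within-group
  identity and low between-group identity, each record tagged with a
  synthetic contig length, so dereplication must recover exactly the
  generated groups.
* :func:`gen_neighborhoods` lays out one anchor CDS per contig, plants
  conserved gene families at fixed CDS offsets with fixed occurrence
  probabilities among mutually dissimilar decoy genes, and writes valid
  GFF3 + FASTA.  This mirrors the statistical structure the relevance score
  assumes: conserved families sit close to the anchor across contexts;
  decoys are context-private.

All randomness flows from one integer seed through a named
``numpy.random.Generator``; regeneration with the same seed is
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import AMINO_ACIDS
from .context import GeneFeature
from .errors import ParameterError
from .screen import SeqRecord

# Study-condition defaults: 88 anchor contexts (dereplicated homolog
# clusters), conserved families within a few CDS of the anchor, windows of
# ~20 genes either side at typical bacterial gene density.
DEFAULT_N_CONTEXTS = 88
DEFAULT_WITHIN_IDENTITY = 0.97
DEFAULT_BETWEEN_IDENTITY_MAX = 0.40
DEFAULT_PLANTED_IDENTITY = 0.80  # to the family base sequence (pairwise >= ~0.6)
CONTIG_LEN_RANGE = (5_000, 200_000)  # log-uniform draw, bases


@dataclass(frozen=True)
class PlantedFamily:
    family_id: str
    offset: int  # CDS-rank offset from the anchor; nonzero
    probability: float  # per-context occurrence probability

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ParameterError("planted family offset must be nonzero")
        if not 0.0 <= self.probability <= 1.0:
            raise ParameterError("occurrence probability must be in [0, 1]")


@dataclass
class TruthBundle:
    """Ground truth emitted alongside every synthetic fixture."""

    homolog_groups: list[tuple[str, list[str], float]] = field(default_factory=list)
    planted_families: list[PlantedFamily] = field(default_factory=list)
    decoy_rate: float = 0.0
    seed: int = 0
    # gene id -> truth family label ("anchor", planted family id, or "decoy:<id>")
    gene_family: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[str] = set()
        for _, members, _ in self.homolog_groups:
            for m in members:
                if m in seen:
                    raise ParameterError(f"member {m} appears in more than one group")
                seen.add(m)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_to_identity(seq: str, target_identity: float, seed: int | np.random.Generator = 0) -> str:
    """Substitute residues so the result has ~``target_identity`` to ``seq``.

    Length is preserved (substitutions only, drawn uniformly from the 19
    alternative residues), so the alignment identity to the input is
    (L - substitutions) / L, within rounding of the target.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ParameterError("target identity must be in (0, 1]")
    if len(seq) < 20:
        raise ParameterError("sequence must be at least 20 residues")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = round(len(seq) * (1.0 - target_identity))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def gen_homolog_set(
    n_groups: int,
    members_per_group: int | tuple[int, int],
    within_identity: float = DEFAULT_WITHIN_IDENTITY,
    between_identity_max: float = DEFAULT_BETWEEN_IDENTITY_MAX,
    seed: int = 0,
    length_range: tuple[int, int] = (150, 300),
) -> tuple[list[SeqRecord], TruthBundle]:
    """Protein groups whose greedy dereplication must recover the truth.

    Each group descends from an independent random base sequence (group
    member 1), with the other members mutated to ``within_identity`` against
    the base; unrelated random bases keep between-group identity far below
    ``between_identity_max``.  Records carry a log-uniform synthetic contig
    length so longest-contig representative selection is exercised.
    """
    if n_groups < 1:
        raise ParameterError("n_groups must be >= 1")
    if not within_identity > between_identity_max:
        raise ParameterError(
            "within-group identity must exceed the between-group maximum "
            f"({within_identity} <= {between_identity_max})"
        )
    rng = np.random.default_rng(seed)
    lo, hi = (
        (members_per_group, members_per_group)
        if isinstance(members_per_group, int)
        else members_per_group
    )
    records: list[SeqRecord] = []
    truth = TruthBundle(seed=seed)
    for g in range(n_groups):
        base = random_protein(rng, int(rng.integers(length_range[0], length_range[1] + 1)))
        size = int(rng.integers(lo, hi + 1))
        member_ids = []
        for m in range(size):
            mid = f"g{g:03d}m{m:02d}"
            seq = base if m == 0 else mutate_to_identity(base, within_identity, rng)
            contig_len = int(
                np.exp(rng.uniform(np.log(CONTIG_LEN_RANGE[0]), np.log(CONTIG_LEN_RANGE[1])))
            )
            records.append(SeqRecord(id=mid, seq=seq, contig_length=contig_len))
            member_ids.append(mid)
        truth.homolog_groups.append((f"g{g:03d}", member_ids, within_identity))
    truth.validate()
    return records, truth


@dataclass
class NeighborhoodFixture:
    """Contigs with annotated CDS features, protein sequences, and truth."""

    features: list[GeneFeature]
    proteins: dict[str, str]
    contig_sequences: dict[str, str]
    contig_lengths: dict[str, int]
    anchor_ids: list[str]
    truth: TruthBundle


def gen_neighborhoods(
    n_contexts: int = DEFAULT_N_CONTEXTS,
    planted: list[PlantedFamily] | list[tuple[str, int, float]] = (),
    window_genes: int = 5,
    decoy_rate: float = 3.0,
    seed: int = 0,
    gene_length: int = 900,
    conserved_gap: int = 100,
    decoy_gap: int = 2_000,
    anchor_identity: float = 0.80,
    planted_identity: float = DEFAULT_PLANTED_IDENTITY,
    protein_length: int = 120,
) -> NeighborhoodFixture:
    """Anchor-centered contigs with planted conserved families among decoys.

    Each context is one contig holding an anchor CDS with up to
    ``window_genes`` CDS slots either side.  A planted family occupies its
    stated offset with its stated probability; members across contexts are
    mutated copies of a family base sequence (pairwise identity well above
    the family-clustering regime).  Remaining slots hold decoy genes
    (expected ``decoy_rate`` per window, mutually unrelated random
    sequences).  Genes in planted slots sit at small intergenic gaps
    (``conserved_gap``); decoy slots use ``decoy_gap``, so conserved regions
    also look compact in base pairs.
    """
    if n_contexts < 2:
        raise ParameterError("n_contexts must be >= 2")
    planted = [PlantedFamily(*p) if isinstance(p, tuple) else p for p in planted]
    offsets_seen: set[int] = set()
    for fam in planted:
        if abs(fam.offset) > window_genes:
            raise ParameterError(
                f"planted offset {fam.offset} outside +-{window_genes} window"
            )
        if fam.offset in offsets_seen:
            raise ParameterError(f"duplicate planted offset {fam.offset}")
        offsets_seen.add(fam.offset)
    if decoy_rate < 0:
        raise ParameterError("decoy_rate must be >= 0")

    rng = np.random.default_rng(seed)
    anchor_base = random_protein(rng, protein_length * 2)
    family_bases = {fam.family_id: random_protein(rng, protein_length) for fam in planted}
    by_offset = {fam.offset: fam for fam in planted}

    truth = TruthBundle(planted_families=planted, decoy_rate=decoy_rate, seed=seed)
    features: list[GeneFeature] = []
    proteins: dict[str, str] = {}
    contig_sequences: dict[str, str] = {}
    contig_lengths: dict[str, int] = {}
    anchor_ids: list[str] = []
    decoy_counter = 0

    for ctx in range(n_contexts):
        contig = f"ctx{ctx:03d}"
        slots: list[tuple[int, str, str]] = []  # (offset, gene id, family label)
        for offset in range(-window_genes, window_genes + 1):
            if offset == 0:
                gid = f"{contig}_anchor"
                slots.append((0, gid, "anchor"))
                proteins[gid] = mutate_to_identity(anchor_base, anchor_identity, rng)
                anchor_ids.append(gid)
                continue
            fam = by_offset.get(offset)
            if fam is not None and rng.random() < fam.probability:
                gid = f"{contig}_f{fam.family_id}"
                slots.append((offset, gid, fam.family_id))
                proteins[gid] = mutate_to_identity(
                    family_bases[fam.family_id], planted_identity, rng
                )

        # decoys fill free slots at the expected per-window rate
        free = [
            o for o in range(-window_genes, window_genes + 1)
            if o != 0 and o not in {s[0] for s in slots}
        ]
        n_decoys = min(int(rng.poisson(decoy_rate)), len(free))
        for offset in sorted(rng.choice(free, size=n_decoys, replace=False).tolist()):
            gid = f"{contig}_d{decoy_counter:04d}"
            decoy_counter += 1
            slots.append((offset, gid, f"decoy:{gid}"))
            proteins[gid] = random_protein(rng, protein_length)

        slots.sort(key=lambda s: s[0])
        # occupied slots are laid out consecutively along the contig
        pos = 1 + int(rng.integers(0, 200))
        for offset, gid, label in slots:
            strand = "+" if rng.random() < 0.7 else "-"
            start = pos
            end = start + gene_length - 1
            features.append(
                GeneFeature(
                    contig_id=contig, start=start, end=end, strand=strand, protein_id=gid
                )
            )
            truth.gene_family[gid] = label
            gap = conserved_gap if (offset in by_offset or offset == 0) else decoy_gap
            pos = end + 1 + gap
        contig_len = pos + int(rng.integers(100, 500))
        contig_lengths[contig] = contig_len
        contig_sequences[contig] = "".join(rng.choice(list("ACGT"), size=contig_len))

    return NeighborhoodFixture(
        features=features,
        proteins=proteins,
        contig_sequences=contig_sequences,
        contig_lengths=contig_lengths,
        anchor_ids=anchor_ids,
        truth=truth,
    )


def write_fasta(seqs: dict[str, str], path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """FASTA wrapped at 60 columns; optional ``contig_len=`` header tag."""
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            tag = ""
            if contig_lengths and sid in contig_lengths:
                tag = f" contig_len={contig_lengths[sid]}"
            fh.write(f">{sid}{tag}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_gff3(features: list[GeneFeature], path: str | Path,
               contig_lengths: dict[str, int] | None = None) -> None:
    """GFF3 (1-based, inclusive) with one CDS line per gene feature."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if contig_lengths:
            for contig, length in contig_lengths.items():
                fh.write(f"##sequence-region {contig} 1 {length}\n")
        for f in sorted(features, key=lambda x: (x.contig_id, x.start)):
            fh.write(
                f"{f.contig_id}\tazescan_synth\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0"
                f"\tID={f.protein_id}\n"
            )


def write_truth_table(truth: TruthBundle, path: str | Path) -> None:
    """Tab-separated ground truth: gene_id, truth_family."""
    with open(path, "w") as fh:
        fh.write("gene_id\ttruth_family\n")
        for gid, label in truth.gene_family.items():
            fh.write(f"{gid}\t{label}\n")
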