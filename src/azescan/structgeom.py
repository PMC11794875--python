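"""Structure parsing and rigid-body geometry: distances, Kabsch RMSD, Cα pairing.

Supports the quantitative geometry of the crystallographic comparison
between ligand complexes of the AZE synthases: the nucleophile-electrophile
(N···Cγ) separation within a bound ligand, and the all-atom least-squares
superposition RMSD over paired Cα atoms between two models of the same
protein.

Same-protein superpositions pair Cα atoms by residue identity
(chain, residue number, insertion code); no sequence alignment is
performed, so cross-protein comparisons require externally paired
coordinates fed straight to :func:`kabsch_superpose`.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .errors import DataError, FormatError, SelectionError

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


@dataclass(frozen=True)
class Atom:
    chain: str
    res_num: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    altloc: str
    occupancy: float
    xyz: tuple[float, float, float]
    is_water: bool

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class StructureModel:
    """Flat atom list of model 1 of a PDB entry, altlocs resolved."""

    pdb_id: str
    atoms: list[Atom]

    def select(self, chain: str, residue: str, atom_name: str) -> list[Atom]:
        """Atoms matching a chain / residue / atom-name triple.

        ``residue`` matches either the residue name (e.g. ``"SAH"``) or the
        residue number as text (e.g. ``"134"``).
        """
        out = []
        for a in self.atoms:
            if a.chain != chain or a.atom_name != atom_name:
                continue
            if a.res_name == residue or str(a.res_num) == residue:
                out.append(a)
        return out

    def ca_atoms(self) -> dict[tuple[str, int, str], Atom]:
        return {
            (a.chain, a.res_num, a.icode): a
            for a in self.atoms
            if a.atom_name == "CA" and not a.is_water
        }


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    # Highest occupancy wins; ties go to altloc 'A' (lexicographically smallest).
    best: dict[tuple[str, int, str, str, str], Atom] = {}
    order: list[tuple[str, int, str, str, str]] = []
    for a in atoms:
        key = (a.chain, a.res_num, a.icode, a.res_name, a.atom_name)
        cur = best.get(key)
        if cur is None:
            best[key] = a
            order.append(key)
        elif (a.occupancy, _altloc_rank(a.altloc)) > (cur.occupancy, _altloc_rank(cur.altloc)):
            best[key] = a
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # Higher rank = preferred on occupancy tie; '' sorts above any letter,
    # then 'A' > 'B' > ...
    if altloc == "":
        return 0.0
    return -ord(altloc)


def read_structure(source: str, pdb_id: str = "") -> StructureModel:
    """Parse PDB-format text (a path or raw text) into a :class:`StructureModel`.

    Only model 1 of multi-model files is kept.  Alternate locations are
    resolved to the highest-occupancy conformer (ties to identifier 'A').
    Waters are retained but flagged.
    """
    try:
        if "\n" in source or source.lstrip().startswith(("ATOM", "HETATM", "HEADER", "CRYST1")):
            structure = gemmi.read_pdb_string(source)
        else:
            structure = gemmi.read_pdb(source)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse PDB input: {exc}") from exc
    if len(structure) == 0:
        raise FormatError("no models in PDB input")
    model = structure[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            is_water = residue.name in WATER_NAMES
            for atom in residue:
                pos = atom.pos
                if not all(np.isfinite([pos.x, pos.y, pos.z])):
                    raise FormatError(
                        f"non-finite coordinate for atom {atom.name} in "
                        f"{chain.name}/{residue.name}{residue.seqid.num}"
                    )
                atoms.append(
                    Atom(
                        chain=chain.name,
                        res_num=residue.seqid.num,
                        icode=(residue.seqid.icode or " ").strip(),
                        res_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        altloc=atom.altloc.strip() if atom.altloc else "",
                        occupancy=float(atom.occ),
                        xyz=(pos.x, pos.y, pos.z),
                        is_water=is_water,
                    )
                )
    if not atoms:
        raise FormatError("no atoms in PDB input")
    return StructureModel(pdb_id=pdb_id or (structure.name or ""), atoms=_resolve_altlocs(atoms))


def _resolve_one(model: StructureModel, selection: tuple[str, str, str]) -> Atom:
    matches = model.select(*selection)
    if not matches:
        raise SelectionError(f"selection {selection} matches no atom")
    if len(matches) > 1:
        listing = ", ".join(
            f"{a.chain}/{a.res_name}{a.res_num}{a.icode}/{a.atom_name}" for a in matches
        )
        raise SelectionError(f"selection {selection} is ambiguous: {listing}")
    return matches[0]


def atom_distance(
    model: StructureModel,
    sel_a: tuple[str, str, str],
    sel_b: tuple[str, str, str],
    precision: int | None = 1,
) -> float:
    """Euclidean distance (Å) between two uniquely selected atoms.

    Selections are (chain, residue name-or-number, atom name).  Reported to
    0.1 Å by default, matching crystallographic convention; pass
    ``precision=None`` for full precision.
    """
    a = _resolve_one(model, sel_a)
    b = _resolve_one(model, sel_b)
    d = float(np.linalg.norm(a.coord - b.coord))
    return round(d, precision) if precision is not None else d


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A (Kabsch, via SVD).

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_b @ rotation.T + translation`` minimizes the RMSD to
    ``coords_a``.  The rotation is proper (reflection-corrected).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise DataError("coordinate arrays must be paired n x 3")
    n = a.shape[0]
    if n < 3:
        raise DataError("need at least 3 paired atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-10) == 0 or np.linalg.matrix_rank(b0, tol=1e-10) == 0:
        raise DataError("degenerate point cloud: all points coincide")
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ca - rotation @ cb
    moved = b @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - a) ** 2).sum() / n))
    return rotation, translation, rmsd


def pair_ca(model_a: StructureModel, model_b: StructureModel) -> tuple[np.ndarray, np.ndarray, int]:
    """Cα coordinate pairs shared by residue identity between two models.

    Pairing key is (chain id, residue number, insertion code).  Returns the
    two coordinate arrays in a matched order plus the pair count; zero
    shared Cα atoms raise :class:`DataError`.
    """
    ca_a = model_a.ca_atoms()
    ca_b = model_b.ca_atoms()
    shared = sorted(set(ca_a) & set(ca_b))
    if not shared:
        raise DataError("no Cα atoms shared by residue identity between the two models")
    xa = np.array([ca_a[k].xyz for k in shared], dtype=float)
    xb = np.array([ca_b[k].xyz for k in shared], dtype=float)
    return xa, xb, len(shared)


def ca_rmsd(model_a: StructureModel, model_b: StructureModel) -> tuple[float, int]:
    """Cα superposition RMSD (Å) and the number of paired Cα atoms."""
    xa, xb, n = pair_ca(model_a, model_b)
    _, _, rmsd = kabsch_superpose(xa, xb)
    return rmsd, n
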