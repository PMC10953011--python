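"""Active-site geometry of protein-ligand complexes.

Reads PDB/mmCIF coordinates (via gemmi), lists protein-ligand contacts by
distance criteria, measures ligand-to-flavin-N5 distances, and computes
backbone-superposition RMSD between two structures with the Kabsch
algorithm.  Written for the NfsA-fumarate complex — a dicarboxylate stacked
over the FMN ring, held by an arginine salt bridge from one subunit and
hydrogen bonds to the flavin ribityl O2' and a backbone amide of the other
subunit — but the operations are generic.

The deposited NfsA-fumarate crystal has one subunit in the asymmetric unit;
the second subunit of the physiological dimer (the "primed" residues) is
recovered by applying the crystallographic symmetry operators
(``expand_crystal_symmetry``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Contact",
    "ContactReport",
    "Superposition",
    "read_structure",
    "expand_crystal_symmetry",
    "superpose_backbone",
    "ligand_contacts",
    "distance_to_flavin_n5",
    "transform_model",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}
#: Side-chain nitrogen atoms that can form salt bridges with a carboxylate.
BASIC_SIDECHAIN_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue address and Cartesian coordinates (Angstrom)."""

    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    altloc: str
    occupancy: float
    pos: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.pos, dtype=float)
        object.__setattr__(self, "pos", pos)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")


@dataclass
class StructureModel:
    """An ordered collection of atoms with optional crystal metadata."""

    atoms: list[AtomRecord]
    name: str = ""
    spacegroup: str | None = None
    cell: tuple[float, float, float, float, float, float] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Atoms grouped by (chain, residue number, residue name)."""
        groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for atom in self.atoms:
            groups.setdefault((atom.chain, atom.res_seq, atom.res_name), []).append(atom)
        return groups

    def select_residue_name(self, res_name: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.res_name == res_name]

    def coordinates(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])


def read_structure(path: str | Path, keep_altloc: str = "highest-occupancy") -> StructureModel:
    """Parse a PDB (or mmCIF) file into a :class:`StructureModel`.

    All ATOM and HETATM records of the first model are kept.  Where a
    residue has alternate conformations, the default policy retains the
    highest-occupancy location of each atom (``keep_altloc="all"`` keeps
    every location).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ValueError(f"{path} contains no atoms")

    atoms: list[AtomRecord] = []
    for chain in st[0]:
        for residue in chain:
            per_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                per_name.setdefault(atom.name, []).append(atom)
            for name, alts in per_name.items():
                if keep_altloc == "all":
                    chosen = alts
                else:
                    chosen = [max(alts, key=lambda a: a.occ)]
                for atom in chosen:
                    atoms.append(
                        AtomRecord(
                            name=name,
                            element=atom.element.name,
                            res_name=residue.name,
                            res_seq=residue.seqid.num,
                            chain=chain.name,
                            altloc=atom.altloc or "",
                            occupancy=min(max(atom.occ, 0.0), 1.0),
                            pos=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        )
                    )
    cell = st.cell
    has_cell = cell is not None and cell.a > 1.0
    return StructureModel(
        atoms=atoms,
        name=st.name or path.stem,
        spacegroup=st.spacegroup_hm or None,
        cell=(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma) if has_cell else None,
    )


def expand_crystal_symmetry(model: StructureModel) -> StructureModel:
    """Add symmetry-mate copies of every chain (crystallographic operators).

    Needed when the biological dimer spans a crystallographic symmetry axis
    so that only one subunit is deposited.  Mate chains are named
    ``<chain>~<op index>``.  Requires cell and space-group metadata.
    """
    if model.cell is None or model.spacegroup is None:
        raise ValueError("symmetry expansion needs unit-cell and space-group metadata")
    sg = gemmi.find_spacegroup_by_name(model.spacegroup)
    if sg is None:
        raise ValueError(f"unknown space group {model.spacegroup!r}")
    cell = gemmi.UnitCell(*model.cell)
    expanded = list(model.atoms)
    for idx, op in enumerate(sg.operations()):
        if op.triplet() == "x,y,z":
            continue
        for atom in model.atoms:
            frac = cell.fractionalize(gemmi.Position(*atom.pos))
            moved = op.apply_to_xyz([frac.x, frac.y, frac.z])
            pos = cell.orthogonalize(gemmi.Fractional(*moved))
            expanded.append(
                AtomRecord(
                    name=atom.name,
                    element=atom.element,
                    res_name=atom.res_name,
                    res_seq=atom.res_seq,
                    chain=f"{atom.chain}~{idx}",
                    altloc=atom.altloc,
                    occupancy=atom.occupancy,
                    pos=np.array([pos.x, pos.y, pos.z]),
                )
            )
    return StructureModel(expanded, model.name + "+sym", model.spacegroup, model.cell)


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid-body superposition: x_fixed ~ rotation @ x_moving + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int


def _kabsch(fixed: np.ndarray, moving: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation + translation mapping moving onto fixed."""
    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    return rot, trans


def superpose_backbone(
    fixed: StructureModel,
    moving: StructureModel,
    atom_names: Sequence[str] = ("CA",),
    chains: Sequence[str] | None = None,
) -> Superposition:
    """Superpose backbone atoms of ``moving`` onto ``fixed`` (Kabsch).

    Atoms are paired by (chain, residue number, atom name) over the
    residues common to both models; if the two models share no chain ids
    but are each single-chain, pairing falls back to (residue number, atom
    name).  RMSD is over the paired atoms after the optimal transform.
    """
    wanted = set(atom_names)

    def collect(model: StructureModel) -> dict[tuple, np.ndarray]:
        out = {}
        for atom in model.atoms:
            if atom.name in wanted and (chains is None or atom.chain in chains):
                out[(atom.chain, atom.res_seq, atom.name)] = atom.pos
        return out

    map_f = collect(fixed)
    map_m = collect(moving)
    common = sorted(set(map_f) & set(map_m))
    if not common:
        chains_f = {k[0] for k in map_f}
        chains_m = {k[0] for k in map_m}
        if len(chains_f) == 1 and len(chains_m) == 1:
            map_f = {k[1:]: v for k, v in map_f.items()}
            map_m = {k[1:]: v for k, v in map_m.items()}
            common = sorted(set(map_f) & set(map_m))
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired backbone atoms, found {len(common)}")

    xf = np.array([map_f[k] for k in common])
    xm = np.array([map_m[k] for k in common])
    rot, trans = _kabsch(xf, xm)
    moved = xm @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - xf) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(common))


@dataclass(frozen=True)
class Contact:
    """One protein(or cofactor)-ligand contact within its category's cutoff."""

    partner: AtomRecord
    ligand_atom: AtomRecord
    distance: float
    category: str  # hydrogen-bond | salt-bridge | nonpolar/stacking


@dataclass
class ContactReport:
    ligand_res_name: str
    contacts: list[Contact] = field(default_factory=list)

    def by_category(self, category: str) -> list[Contact]:
        return [c for c in self.contacts if c.category == category]

    def partner_residues(self) -> set[tuple[str, int, str]]:
        return {
            (c.partner.chain, c.partner.res_seq, c.partner.res_name) for c in self.contacts
        }

    def as_records(self) -> list[dict]:
        return [
            {
                "category": c.category,
                "ligand_atom": c.ligand_atom.name,
                "partner_chain": c.partner.chain,
                "partner_res": c.partner.res_name,
                "partner_seq": c.partner.res_seq,
                "partner_atom": c.partner.name,
                "distance_A": round(c.distance, 3),
            }
            for c in self.contacts
        ]


def ligand_contacts(
    model: StructureModel,
    ligand_res_name: str = "FUM",
    hb_cutoff: float = 3.5,
    sb_cutoff: float = 4.0,
    nonpolar_cutoff: float = 4.0,
    include_waters: bool = False,
) -> ContactReport:
    """Distance-based contact inventory around a bound ligand.

    Hydrogen bonds: ligand O/N to any O/N of another residue within
    ``hb_cutoff``.  Salt bridges: ligand O to a basic side-chain N
    (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2) within ``sb_cutoff``; such pairs
    are reported once, as salt bridges.  Nonpolar/stacking: ligand C to any
    C within ``nonpolar_cutoff``.  Criteria are distance-only since
    crystallographic models usually lack hydrogens.  Waters are excluded by
    default.
    """
    ligand = model.select_residue_name(ligand_res_name)
    if not ligand:
        raise ValueError(f"ligand residue {ligand_res_name!r} not found in model")
    ligand_keys = {(a.chain, a.res_seq) for a in ligand}
    others = [
        a
        for a in model.atoms
        if a.res_name != ligand_res_name
        and (a.chain, a.res_seq) not in ligand_keys
        and (include_waters or a.res_name not in WATER_NAMES)
    ]
    report = ContactReport(ligand_res_name)
    for la in ligand:
        for pa in others:
            dist = float(np.linalg.norm(la.pos - pa.pos))
            if dist <= 0:
                continue
            is_salt = (
                la.element == "O"
                and pa.name in BASIC_SIDECHAIN_N.get(pa.res_name, set())
                and dist <= sb_cutoff
            )
            if is_salt:
                report.contacts.append(Contact(pa, la, dist, "salt-bridge"))
                continue
            if la.element in ("O", "N") and pa.element in ("O", "N") and dist <= hb_cutoff:
                report.contacts.append(Contact(pa, la, dist, "hydrogen-bond"))
                continue
            if la.element == "C" and pa.element == "C" and dist <= nonpolar_cutoff:
                report.contacts.append(Contact(pa, la, dist, "nonpolar/stacking"))
    report.contacts.sort(key=lambda c: c.distance)
    return report


def distance_to_flavin_n5(
    model: StructureModel,
    ligand_res_name: str = "FUM",
    central_atoms: Sequence[str] = ("C2", "C3"),
    flavin_res_name: str = "FMN",
) -> list[float]:
    """Distances (Angstrom, ascending) from the ligand's central carbons to FMN N5.

    For fumarate the central atoms are C2 and C3, the olefinic carbons that
    stack over the flavin; their separation from N5 is the geometry relevant
    to hydride transfer.  Raises naming any missing atom.
    """
    n5 = [a for a in model.select_residue_name(flavin_res_name) if a.name == "N5"]
    if not n5:
        raise ValueError(f"no atom N5 in residue {flavin_res_name!r}")
    ligand = model.select_residue_name(ligand_res_name)
    if not ligand:
        raise ValueError(f"ligand residue {ligand_res_name!r} not found in model")
    by_name = {a.name: a for a in ligand}
    missing = [name for name in central_atoms if name not in by_name]
    if missing:
        raise ValueError(
            f"ligand {ligand_res_name!r} is missing central atoms {missing}"
        )
    # with symmetry mates there may be several N5 copies; use the nearest
    distances = [
        min(float(np.linalg.norm(by_name[name].pos - n.pos)) for n in n5)
        for name in central_atoms
    ]
    return sorted(distances)


def transform_model(model: StructureModel, rotation: np.ndarray, translation: np.ndarray) -> StructureModel:
    """Apply a rigid transform to every atom (convenience for tests and checks)."""
    atoms = [
        AtomRecord(
            name=a.name,
            element=a.element,
            res_name=a.res_name,
            res_seq=a.res_seq,
            chain=a.chain,
            altloc=a.altloc,
            occupancy=a.occupancy,
            pos=rotation @ a.pos + translation,
        )
        for a in model.atoms
    ]
    return StructureModel(atoms, model.name, model.spacegroup, model.cell)
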