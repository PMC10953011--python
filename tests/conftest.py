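"""Shared fixtures: published parameter sets and programmatically built
PDB fixtures (all structural fixtures are synthetic, constructed in-memory)."""

from __future__ import annotations

import numpy as np
import pytest

from nitrokin.rate_laws import KineticParameters
from nitrokin.structure import StructureModel, read_structure


@pytest.fixture
def fumarate_params() -> KineticParameters:
    """Global estimates for NfsA with fumarate (kcat s^-1, Km/Ki uM)."""
    return KineticParameters(kcat=25.0, km_a=27.0, km_b=29.0, ki_a=960.0, ki_b=145.0)


@pytest.fixture
def succinate_params() -> KineticParameters:
    """Global estimates for NfsA with succinate: no inhibition on the NFZ half."""
    return KineticParameters(kcat=51.0, km_a=58.0, km_b=69.0, ki_a=None, ki_b=4300.0)


@pytest.fixture
def nfsb_params() -> KineticParameters:
    """Uninhibited NfsB-like parameter set."""
    return KineticParameters(kcat=36.0, km_a=20.0, km_b=32.0)


def pdb_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_seq: int,
    xyz,
    element: str,
    het: bool = True,
    occupancy: float = 1.0,
    altloc: str = " ",
) -> str:
    record = "HETATM" if het else "ATOM  "
    padded = name if len(name) == 4 else f" {name:<3}"
    x, y, z = xyz
    return (
        f"{record}{serial:>5} {padded}{altloc}{res_name:<3} {chain}{res_seq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00          {element:>2}"
    )


def write_pdb(path, lines, cryst1: str | None = None) -> None:
    content = []
    if cryst1:
        content.append(cryst1)
    content.extend(lines)
    content.append("END")
    path.write_text("\n".join(content) + "\n")


def build_site_mimic(tmp_path) -> StructureModel:
    """Synthetic active-site mimic of a dicarboxylate bound over a flavin.

    Entirely constructed geometry (not deposited coordinates): a fumarate
    whose olefinic carbons sit 3.2 and 3.6 A from the flavin N5, one
    carboxylate oxygen 2.80 A from an arginine NH1 (chain A, residue 225)
    and near a second arginine (133) and glycine (130), the other
    carboxylate hydrogen-bonded to the flavin ribityl O2' (2.74 A) and a
    serine backbone amide on the partner subunit (chain B, residue 41,
    2.90 A).  A water oxygen is placed nearby to exercise water exclusion.
    """
    c2 = np.array([0.0, 0.0, 3.2])
    c3 = np.array([1.3217, 0.0, 3.3486])
    c1 = c2 + [-1.33, 0.55, 0.30]
    o1 = c1 + [-1.00, 0.65, 0.15]
    o2 = c1 + [-0.35, -1.15, 0.45]
    c4 = c3 + [1.35, 0.55, 0.25]
    o3 = c4 + [0.95, 0.75, 0.10]
    o4 = c4 + [0.75, -0.95, 0.35]
    nh1_225 = o1 + [-2.00, 1.96, 0.0]  # 2.80 A salt bridge
    cz_225 = nh1_225 + [-1.00, 0.80, 0.0]
    nh2_225 = cz_225 + [-0.50, -1.20, 0.20]
    ne_225 = cz_225 + [-0.20, 1.30, -0.40]
    nh1_133 = o2 + [0.50, -3.20, 0.50]  # 3.28 A, second salt bridge
    n_130 = o2 + [-0.30, -3.30, 0.80]  # 3.41 A backbone H-bond
    o2prime = o3 + [1.90, 1.98, 0.0]  # 2.74 A H-bond to ribityl hydroxyl
    n_41 = o4 + [2.05, -2.05, 0.0]  # 2.90 A backbone amide H-bond
    ca_41 = n_41 + [1.20, -0.80, 0.30]
    water = o1 + [0.0, 0.0, 2.9]

    lines = [
        pdb_atom_line(1, "N5", "FMN", "A", 300, (0, 0, 0), "N"),
        pdb_atom_line(2, "C4A", "FMN", "A", 300, (0.70, 0.70, -0.20), "C"),
        pdb_atom_line(3, "O2'", "FMN", "A", 300, o2prime, "O"),
        pdb_atom_line(4, "C1", "FUM", "A", 400, c1, "C"),
        pdb_atom_line(5, "O1", "FUM", "A", 400, o1, "O"),
        pdb_atom_line(6, "O2", "FUM", "A", 400, o2, "O"),
        pdb_atom_line(7, "C2", "FUM", "A", 400, c2, "C"),
        pdb_atom_line(8, "C3", "FUM", "A", 400, c3, "C"),
        pdb_atom_line(9, "C4", "FUM", "A", 400, c4, "C"),
        pdb_atom_line(10, "O3", "FUM", "A", 400, o3, "O"),
        pdb_atom_line(11, "O4", "FUM", "A", 400, o4, "O"),
        pdb_atom_line(12, "NE", "ARG", "A", 225, ne_225, "N", het=False),
        pdb_atom_line(13, "CZ", "ARG", "A", 225, cz_225, "C", het=False),
        pdb_atom_line(14, "NH1", "ARG", "A", 225, nh1_225, "N", het=False),
        pdb_atom_line(15, "NH2", "ARG", "A", 225, nh2_225, "N", het=False),
        pdb_atom_line(16, "NH1", "ARG", "A", 133, nh1_133, "N", het=False),
        pdb_atom_line(17, "N", "GLY", "A", 130, n_130, "N", het=False),
        pdb_atom_line(18, "N", "SER", "B", 41, n_41, "N", het=False),
        pdb_atom_line(19, "CA", "SER", "B", 41, ca_41, "C", het=False),
        pdb_atom_line(20, "O", "HOH", "A", 500, water, "O"),
    ]
    # a short CA backbone, placed far from the site, so backbone
    # superposition against this model has enough paired atoms
    for k, pos in enumerate(build_ca_chain(12, seed=3)):
        lines.append(
            pdb_atom_line(21 + k, "CA", "ALA", "A", 1 + k, pos + [50.0, 50.0, 50.0],
                          "C", het=False)
        )
    path = tmp_path / "synthetic_site_mimic.pdb"
    write_pdb(path, lines)
    return read_structure(path)


@pytest.fixture
def site_mimic(tmp_path) -> StructureModel:
    return build_site_mimic(tmp_path)


def build_ca_chain(n_residues: int = 60, seed: int = 7) -> list[np.ndarray]:
    """Random-walk CA trace with 3.8 A steps (synthetic backbone)."""
    rng = np.random.default_rng(seed)
    positions = [np.zeros(3)]
    for _ in range(n_residues - 1):
        step = rng.standard_normal(3)
        positions.append(positions[-1] + 3.8 * step / np.linalg.norm(step))
    return positions


def ca_model_from_positions(tmp_path, positions, fname: str, chain: str = "A") -> StructureModel:
    lines = [
        pdb_atom_line(k + 1, "CA", "ALA", chain, k + 1, pos, "C", het=False)
        for k, pos in enumerate(positions)
    ]
    path = tmp_path / fname
    write_pdb(path, lines)
    return read_structure(path)
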