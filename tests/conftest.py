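"""Shared fixtures: hand-written PDB texts and seeded synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from perturbnet import SyntheticSpec, end_to_end_dataset
from perturbnet.networks import score_mutant_set
from perturbnet.scoring import average_over_chains, standardize_table


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: tuple[float, float, float],
    element: str,
    altloc: str = " ",
    icode: str = " ",
    occupancy: float = 1.0,
    record: str = "ATOM",
) -> str:
    field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {field}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Three standard residues, one hydrogen, and a water record."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, (0.0, 0.0, 0.0), "N"),
        pdb_line(2, "CA", "ALA", "A", 1, (1.5, 0.0, 0.0), "C"),
        pdb_line(3, "HB1", "ALA", "A", 1, (1.5, 1.0, 0.0), "H"),
        pdb_line(4, "N", "GLY", "A", 2, (3.0, 0.0, 0.0), "N"),
        pdb_line(5, "CA", "GLY", "A", 2, (4.5, 0.0, 0.0), "C"),
        pdb_line(6, "N", "SER", "A", 3, (6.0, 0.0, 0.0), "N"),
        pdb_line(7, "CA", "SER", "A", 3, (7.5, 0.0, 0.0), "C"),
        pdb_line(8, "O", "HOH", "A", 90, (20.0, 20.0, 20.0), "O", record="HETATM"),
        "END",
    ]
    path = tmp_path / "three.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    """Residue 10 with two conformers; B is listed second but more occupied."""
    lines = [
        pdb_line(1, "N", "SER", "A", 10, (0.0, 0.0, 0.0), "N"),
        pdb_line(2, "CA", "SER", "A", 10, (1.5, 0.0, 0.0), "C", altloc="A",
                 occupancy=0.4),
        pdb_line(3, "CA", "SER", "A", 10, (1.6, 0.3, 0.0), "C", altloc="B",
                 occupancy=0.6),
        pdb_line(4, "OG", "SER", "A", 10, (2.0, 1.0, 0.0), "O", altloc="A",
                 occupancy=0.4),
        pdb_line(5, "OG", "SER", "A", 10, (2.1, 1.2, 0.0), "O", altloc="B",
                 occupancy=0.6),
        pdb_line(6, "N", "GLY", "A", 11, (3.0, 0.0, 0.0), "N"),
        pdb_line(7, "CA", "GLY", "A", 11, (4.5, 0.0, 0.0), "C"),
        "END",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    lines = [
        pdb_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), "C"),
        pdb_line(2, "CA", "GLY", "A", 2, (3.8, 0.0, 0.0), "C"),
        pdb_line(3, "CA", "ALA", "B", 1, (0.0, 6.0, 0.0), "C"),
        pdb_line(4, "CA", "GLY", "B", 2, (3.8, 6.0, 0.0), "C"),
        "END",
    ]
    path = tmp_path / "dimer.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def random_toy_structure(rng: np.random.Generator):
    """Random point-cloud structure: <= 10 residues of <= 10 atoms each."""
    from perturbnet.structure_io import Atom, Residue, ResidueID, Structure

    n_res = int(rng.integers(2, 11))
    residues = []
    for i in range(n_res):
        n_atoms = int(rng.integers(1, 11))
        center = rng.uniform(0, 12, size=3)
        coords = center + rng.normal(scale=1.5, size=(n_atoms, 3))
        atoms = [Atom(f"C{k}", tuple(c), "C") for k, c in enumerate(coords)]
        residues.append(Residue(ResidueID("A", i + 1), "ALA", atoms))
    return Structure(residues)


@pytest.fixture(scope="session")
def e2e_dataset():
    """30-residue synthetic study with known sensitive positions (seed 1)."""
    spec = SyntheticSpec(seed=1)
    wt, mutants, func, designated = end_to_end_dataset(spec)
    return wt, mutants, func, designated


@pytest.fixture(scope="session")
def e2e_table(e2e_dataset):
    """Standardized score table of the 30-residue study at t = 9 Å."""
    wt, mutants, _, _ = e2e_dataset
    raw = score_mutant_set(wt, mutants, [9.0])
    return standardize_table(average_over_chains(raw))


@pytest.fixture(scope="session")
def small_multithreshold():
    """10-residue study scored over three thresholds, for sweep machinery."""
    spec = SyntheticSpec(seed=3, n_residues=10)
    wt, mutants, func, designated = end_to_end_dataset(spec)
    raw = score_mutant_set(wt, mutants, [8.0, 9.0, 10.0])
    return average_over_chains(raw), func, designated
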