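"""Synthetic inputs for the full pipeline: structures, mutants, scores.

Real inputs to the method are a wild-type PDB file, a directory of mutant
structures from an external mutagenesis engine, and a deep-mutational-
scanning score table.  This module generates stand-ins for all three so
the pipeline can be exercised and validated end to end:

* toy "proteins": residue centers on a self-avoiding random walk with a
  fixed backbone spacing, each residue a small jittered atom cloud;
* synthetic "mutants": copies of the wild type with the atoms of one
  residue displaced by a controlled magnitude — the perturbation-network
  machinery is agnostic to how a mutant structure arose;
* functional tables with a position-dependent effect (plus noise), which
  is the structure real deep-mutational-scanning data shows: the effect
  of a mutation depends on where it lands, not on which amino acid
  replaces which.

Nothing here claims physical realism: no secondary structure, no side
chains, no energetics.  What it does provide is a dataset whose ground
truth is known by construction, so recovery of the designated sensitive
positions is a meaningful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import AminoAcidNetwork, Mutation
from .structure_io import (
    AA1_TO_3,
    AA3_TO_1,
    Atom,
    Residue,
    ResidueID,
    Structure,
)

import networkx as nx

__all__ = [
    "SyntheticSpec",
    "toy_perturbation_example",
    "generate_structure",
    "generate_mutant",
    "generate_functional_table",
    "generate_mutant_set",
    "end_to_end_dataset",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generator (all lengths in Ångstroms).

    Defaults describe a 30-residue toy chain: residue centers 3.8 Å apart
    (the C-alpha—C-alpha virtual bond length), five atoms per residue
    jittered with sd 1.0 Å (a compact side-chain-sized cloud), mutations
    displacing atoms by 2.0 Å (a rotamer-scale rearrangement), and a
    functional table where 40% of positions lose function (effect −2,
    about twenty noise sd below neutral).
    """

    n_residues: int = 30
    atoms_per_residue: int = 5
    backbone_spacing: float = 3.8
    atom_jitter_sd: float = 1.0
    mutation_displacement: float = 2.0
    seed: int = 0
    functional_effect_map: Mapping[int, float] | None = None
    functional_noise_sd: float = 0.1
    sensitive_fraction: float = 0.4
    sensitive_effect: float = -2.0

    def rng(self, *salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, *salt]))


def toy_perturbation_example() -> tuple[AminoAcidNetwork, AminoAcidNetwork]:
    """The three-residue worked example of a perturbation network.

    Wild type: triangle a–b–c with weights (a,b)=4, (b,c)=1, (a,c)=2.
    Mutant (mutation at b): (a,b) drops to 1 (three atom pairs lost) and
    (b,c) disappears; (a,c) is untouched.  The perturbation network then
    has 3 nodes, 2 edges, total weight 4, and diameter 2.
    """
    a = ResidueID("A", 1)
    b = ResidueID("A", 2)
    c = ResidueID("A", 3)
    wt = nx.Graph()
    wt.add_edge(a, b, weight=4)
    wt.add_edge(b, c, weight=1)
    wt.add_edge(a, c, weight=2)
    mut = nx.Graph()
    mut.add_edge(a, b, weight=1)
    mut.add_edge(a, c, weight=2)
    mut.add_nodes_from([a, b, c])
    return AminoAcidNetwork(9.0, wt), AminoAcidNetwork(9.0, mut)


def _self_avoiding_walk(
    n: int, step: float, rng: np.random.Generator, min_sep_factor: float = 0.9
) -> np.ndarray:
    """Residue centers: confined fixed-step 3D walk avoiding self-approaches.

    The walk is confined to a sphere whose radius scales as n^(1/3), so the
    chain collapses into a compact globule rather than an open coil —
    without the confinement, chain termini would sit in much sparser
    contact neighborhoods than interior residues.
    """
    centers = [np.zeros(3)]
    min_sep = min_sep_factor * step
    radius = 0.7 * step * n ** (1.0 / 3.0)
    while len(centers) < n:
        placed = False
        for _ in range(500):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = centers[-1] + step * direction
            earlier = np.array(centers[:-1]).reshape(-1, 3)
            dists = np.linalg.norm(earlier - cand, axis=1)
            if (dists > min_sep).all() and np.linalg.norm(cand) <= radius:
                centers.append(cand)
                placed = True
                break
        if not placed:  # pragma: no cover - walk got stuck, relax confinement
            radius *= 1.1
    return np.array(centers)


def generate_structure(spec: SyntheticSpec, chain: str = "A") -> Structure:
    """Generate a toy wild-type structure, deterministic under the seed.

    Residue amino-acid types are drawn uniformly (they matter only for
    mutation labels and synonymous bookkeeping, never for geometry).
    """
    rng = spec.rng(1)
    centers = _self_avoiding_walk(spec.n_residues, spec.backbone_spacing, rng)
    aa_codes = rng.choice(sorted(AA1_TO_3), size=spec.n_residues)
    residues = []
    for i, center in enumerate(centers):
        atoms = [Atom("CA", tuple(center), "C")]
        jitter = rng.normal(scale=spec.atom_jitter_sd,
                            size=(spec.atoms_per_residue - 1, 3))
        for k, offset in enumerate(jitter, start=1):
            atoms.append(Atom(f"C{k}", tuple(center + offset), "C"))
        residues.append(
            Residue(ResidueID(chain, i + 1), AA1_TO_3[str(aa_codes[i])], atoms)
        )
    return Structure(residues)


def generate_mutant(
    wt: Structure,
    position: int,
    spec: SyntheticSpec,
    chain: str = "A",
    salt: int = 0,
) -> Structure:
    """Copy of ``wt`` with the atoms of one residue displaced.

    Each atom of the residue moves by an independent random direction.
    The magnitude is ``spec.mutation_displacement`` scaled by a severity
    factor drawn once per mutant as 1.75·U(0,1)²: substitutions differ in
    how much they rearrange a site, and the right-skewed spread — most
    mutants structurally mild, a few severe — is what makes the worst
    mutants at a position stand out against the pooled score
    distribution, as in real saturation mutagenesis.  Every other residue
    is untouched and all ResidueIDs are preserved.  ``salt`` distinguishes
    the different mutant amino acids at one position.
    """
    rid = ResidueID(chain, position)
    if rid not in wt.residue_ids():
        raise KeyError(f"position {position} not in wild-type structure")
    rng = spec.rng(2, position, salt)
    magnitude = spec.mutation_displacement * 1.75 * rng.uniform() ** 2
    residues = []
    for res in wt:
        if res.rid == rid and spec.mutation_displacement > 0:
            atoms = []
            for atom in res.atoms:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                moved = np.array(atom.coord) + magnitude * direction
                atoms.append(Atom(atom.name, tuple(moved), atom.element))
            residues.append(Residue(res.rid, res.resname, atoms))
        else:
            residues.append(Residue(res.rid, res.resname, list(res.atoms)))
    return Structure(residues)


def _effect_map(spec: SyntheticSpec, positions: Sequence[int]) -> dict[int, float]:
    if spec.functional_effect_map is not None:
        missing = set(positions) - set(spec.functional_effect_map)
        if missing:
            raise ValueError(f"effect map lacks positions {sorted(missing)}")
        return {p: float(spec.functional_effect_map[p]) for p in positions}
    rng = spec.rng(3)
    k = int(np.floor(len(positions) * spec.sensitive_fraction))
    chosen = rng.choice(len(positions), size=k, replace=False)
    sensitive = {positions[int(i)] for i in chosen}
    return {
        p: (spec.sensitive_effect if p in sensitive else 0.0) for p in positions
    }


def generate_functional_table(
    spec: SyntheticSpec,
    positions: Sequence[int],
    wt_sequence: Sequence[str],
) -> pd.DataFrame:
    """Functional table with a position-dependent effect plus noise.

    Entry (position, mutant aa) = effect(position) + N(0, noise_sd);
    synonymous cells are 0.  Indexed by position with a ``wt_aa`` column
    and one column per mutant amino acid.
    """
    from .prediction import AA_ORDER

    effects = _effect_map(spec, list(positions))
    rng = spec.rng(4)
    rows = []
    for pos, wt_aa in zip(positions, wt_sequence):
        row: dict[str, object] = {"position": pos, "wt_aa": wt_aa}
        for aa in AA_ORDER:
            if aa == wt_aa:
                row[aa] = 0.0
            else:
                row[aa] = effects[pos] + rng.normal(scale=spec.functional_noise_sd)
        rows.append(row)
    return pd.DataFrame(rows).set_index("position")


def generate_mutant_set(
    wt: Structure, spec: SyntheticSpec, displacement_map: Mapping[int, float] | None = None
) -> dict[Mutation, Structure]:
    """All 19 mutants at every position of a (single-chain) toy structure.

    ``displacement_map`` optionally overrides the displacement magnitude
    per position (e.g. large at designated sensitive positions, near zero
    elsewhere).
    """
    from .prediction import AA_ORDER

    chain = wt.residues[0].rid.chain
    mutants: dict[Mutation, Structure] = {}
    for res in wt:
        pos = res.rid.number
        wt_aa = AA3_TO_1[res.resname]
        disp = (
            displacement_map.get(pos, spec.mutation_displacement)
            if displacement_map is not None
            else spec.mutation_displacement
        )
        local = replace(spec, mutation_displacement=disp)
        for salt, aa in enumerate(AA_ORDER):
            if aa == wt_aa:
                continue
            mutation = Mutation(chain, pos, wt_aa, aa)
            mutants[mutation] = generate_mutant(wt, pos, local, chain, salt=salt)
    return mutants


def end_to_end_dataset(
    spec: SyntheticSpec | None = None,
) -> tuple[Structure, dict[Mutation, Structure], pd.DataFrame, set[int]]:
    """A complete synthetic study with known ground truth.

    Returns (wild type, mutants, functional table, designated sensitive
    positions).  The designated positions (``sensitive_fraction`` of the
    chain) get structure-disrupting mutants (full ``mutation_displacement``)
    and a functional effect of ``sensitive_effect``; all other positions
    get near-rigid mutants (displacement 1/40 of the full magnitude) and a
    neutral functional effect.
    """
    spec = spec or SyntheticSpec()
    wt = generate_structure(spec)
    positions = [r.rid.number for r in wt]
    effects = _effect_map(spec, positions)
    designated = {p for p, e in effects.items() if e != 0.0}
    spec = replace(spec, functional_effect_map=effects)
    displacement_map = {
        p: (spec.mutation_displacement if p in designated
            else spec.mutation_displacement / 40.0)
        for p in positions
    }
    mutants = generate_mutant_set(wt, spec, displacement_map)
    wt_sequence = [AA3_TO_1[r.resname] for r in wt]
    func = generate_functional_table(spec, positions, wt_sequence)
    return wt, mutants, func, designated
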