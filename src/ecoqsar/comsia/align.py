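"""Rigid-body superposition of molecules onto a template skeleton.

Each molecule is mapped, atom to atom, onto a common core (for phthalate
esters: the benzene-1,2-diester skeleton) and rigidly rotated/translated to
minimize the RMSD over the mapped pairs (Kabsch least-squares fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from ..chem_core import Molecule3D

__all__ = ["AlignmentSpec", "AlignmentResult", "align_to_template", "core_mapping"]


@dataclass
class AlignmentSpec:
    """Template id plus, per molecule, a list of (mol_atom, template_atom) pairs."""

    template_id: str
    mappings: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def validate(self) -> None:
        for mol_id, pairs in self.mappings.items():
            if len(pairs) < 3:
                raise ValueError(f"{mol_id}: need >= 3 mapped atom pairs, got {len(pairs)}")
            left = [p[0] for p in pairs]
            right = [p[1] for p in pairs]
            if len(set(left)) != len(left) or len(set(right)) != len(right):
                raise ValueError(f"{mol_id}: atom mapping must be injective")


@dataclass
class AlignmentResult:
    molecules: list[Molecule3D]
    rmsd: dict[str, float]


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||R P + t - Q||; proper rotation only."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def align_to_template(mols: list[Molecule3D], spec: AlignmentSpec) -> AlignmentResult:
    """Superpose every molecule onto the template over the mapped core atoms.

    The template itself is left in place (identity transform).  Returns new
    molecule objects with transformed coordinates and the per-molecule core
    RMSD after fitting.
    """
    spec.validate()
    by_id = {m.id: m for m in mols}
    if spec.template_id not in by_id:
        raise KeyError(f"template molecule {spec.template_id!r} not in input set")
    template = by_id[spec.template_id]
    if template.coords is None:
        raise ValueError(f"{template.id}: template has no coordinates")

    aligned, rmsds = [], {}
    for mol in mols:
        if mol.coords is None:
            raise ValueError(f"{mol.id}: no coordinates; embed first")
        if mol.id == spec.template_id:
            aligned.append(mol.copy())
            rmsds[mol.id] = 0.0
            continue
        if mol.id not in spec.mappings:
            raise KeyError(f"no atom mapping for molecule {mol.id!r}")
        pairs = spec.mappings[mol.id]
        if len(pairs) < 3:
            raise ValueError(f"{mol.id}: need >= 3 mapped atom pairs")
        P = mol.coords[[p[0] for p in pairs]]
        Q = template.coords[[p[1] for p in pairs]]
        R, t = _kabsch(P, Q)
        out = mol.copy()
        out.coords = mol.coords @ R.T + t
        aligned.append(out)
        rmsds[mol.id] = float(np.sqrt(((P @ R.T + t - Q) ** 2).sum(axis=1).mean()))
    return AlignmentResult(molecules=aligned, rmsd=rmsds)


def core_mapping(mols: list[Molecule3D], template_id: str,
                 core_smarts: str) -> AlignmentSpec:
    """Build an AlignmentSpec from a shared substructure.

    Matches ``core_smarts`` in the template and in every other molecule and
    pairs the matched atoms positionally.  Atom indices refer to the current
    RDKit molecule of each entry (hydrogens included if embedded).
    """
    patt = Chem.MolFromSmarts(core_smarts)
    if patt is None:
        raise ValueError(f"invalid SMARTS: {core_smarts!r}")
    by_id = {m.id: m for m in mols}
    template = by_id[template_id]
    t_match = template.rdkit_mol.GetSubstructMatch(patt)
    if not t_match:
        raise ValueError(f"{template_id}: template does not match the core")
    mappings = {}
    for mol in mols:
        if mol.id == template_id:
            continue
        match = mol.rdkit_mol.GetSubstructMatch(patt)
        if not match:
            raise ValueError(f"{mol.id}: molecule does not match the core")
        mappings[mol.id] = list(zip(match, t_match))
    return AlignmentSpec(template_id=template_id, mappings=mappings)
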