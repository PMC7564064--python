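"""Similarity-index field descriptors on a regular lattice.

For every lattice point q and field F (steric S, electrostatic E,
hydrophobic H, H-bond donor D, H-bond acceptor A) the descriptor is the
Gaussian-attenuated similarity between a probe atom and the molecule:

    A_F(q) = - sum_atoms  w_probe,F * w_atom,F * exp(-alpha * r_atom,q^2)

with r in Å and alpha the attenuation factor (default 0.3, the conventional
similarity-index choice).  The probe carries charge +1 e, radius 1 Å,
hydrophobicity +1 and donor/acceptor strength +1.  The negative sign follows
the similarity-index convention; linearity in the atomic parameters and
rigid-motion equivariance are the key structural properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..chem_core import Molecule3D

__all__ = ["GridSettings", "FieldGrid", "FIELDS", "compute_fields", "descriptor_matrix"]

FIELDS = ("S", "E", "H", "D", "A")


@dataclass
class GridSettings:
    """Lattice geometry and probe parameters."""

    spacing: float = 2.0  # Å between lattice points
    margin: float = 4.0  # Å padding around the aligned union
    alpha: float = 0.3  # Gaussian attenuation (1/Å^2)
    probe: dict[str, float] = field(
        default_factory=lambda: {"S": 1.0, "E": 1.0, "H": 1.0, "D": 1.0, "A": 1.0}
    )
    fields: tuple[str, ...] = FIELDS


@dataclass
class FieldGrid:
    """A shared lattice plus per-molecule field blocks.

    ``values[mol_id]`` is a dict field -> array of length n_points.  The
    lattice is the axis-aligned box covering all molecules plus the margin.
    """

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    settings: GridSettings
    values: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> np.ndarray:
        """Lattice coordinates, (n_points, 3), x fastest-varying last axis order."""
        axes = [self.origin[k] + self.spacing * np.arange(self.shape[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def encloses(self, mol: Molecule3D) -> bool:
        lo = self.origin
        hi = self.origin + self.spacing * (np.array(self.shape) - 1)
        return bool(np.all(mol.coords >= lo - 1e-9) and np.all(mol.coords <= hi + 1e-9))


def _atom_weights(mol: Molecule3D, f: str) -> np.ndarray:
    if f == "S":
        w = mol.steric_param
    elif f == "E":
        w = mol.partial_charges
    elif f == "H":
        w = mol.hydrophobic_param
    elif f == "D":
        w = mol.donor_flag
    elif f == "A":
        w = mol.acceptor_flag
    else:
        raise ValueError(f"unknown field {f!r}")
    if w is None:
        raise ValueError(f"{mol.id}: per-atom parameters for field {f} not assigned")
    return np.asarray(w, dtype=float)


def make_grid(mols: list[Molecule3D], settings: GridSettings | None = None) -> FieldGrid:
    """Build the lattice enclosing all molecules with the configured margin."""
    settings = settings or GridSettings()
    coords = np.vstack([m.coords for m in mols])
    lo = coords.min(axis=0) - settings.margin
    hi = coords.max(axis=0) + settings.margin
    shape = tuple(int(np.floor((hi[k] - lo[k]) / settings.spacing)) + 1 for k in range(3))
    return FieldGrid(origin=lo, spacing=settings.spacing, shape=shape, settings=settings)


def compute_fields(
    mols: list[Molecule3D],
    settings: GridSettings | None = None,
    grid: FieldGrid | None = None,
) -> FieldGrid:
    """Evaluate the similarity-index fields of every molecule on one lattice.

    If ``grid`` is given (e.g. the training grid when describing new
    molecules) it must enclose every molecule; otherwise a fresh lattice is
    built around the input set.
    """
    settings = settings if settings is not None else (grid.settings if grid else GridSettings())
    if grid is None:
        grid = make_grid(mols, settings)
    pts = grid.points()
    for mol in mols:
        if mol.coords is None:
            raise ValueError(f"{mol.id}: no coordinates")
        if not grid.encloses(mol):
            raise ValueError(f"{mol.id}: molecule outside the field lattice")
        # (n_points, n_atoms) squared distances -> shared Gaussian kernel
        d2 = ((pts[:, None, :] - mol.coords[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-settings.alpha * d2)
        blocks = {}
        for f in settings.fields:
            w = _atom_weights(mol, f)
            blocks[f] = -settings.probe[f] * (K @ w)
        grid.values[mol.id] = blocks
    return grid


def descriptor_matrix(
    grid: FieldGrid, ids: list[str], fields: tuple[str, ...] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-molecule field blocks into (X, field_labels).

    X has one row per molecule and one column per (field, lattice point),
    blocks concatenated in field order; ``field_labels`` names the field of
    each column.
    """
    fields = fields or grid.settings.fields
    rows = []
    for mol_id in ids:
        if mol_id not in grid.values:
            raise KeyError(f"no fields computed for {mol_id!r}")
        rows.append(np.concatenate([grid.values[mol_id][f] for f in fields]))
    labels = np.concatenate([np.full(grid.n_points, f) for f in fields])
    return np.vstack(rows), labels
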