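"""Structure parsing, 3D conformer preparation, and per-atom field parameters.

Everything downstream (field grids, alignment, derivative enumeration) works
on :class:`Molecule3D`, a plain array container.  RDKit does the chemistry:
SMILES/MOL parsing, ETKDG embedding, MMFF94 minimization, Gasteiger charges,
and Crippen atomic logP contributions.  The per-atom parameters are the
molecule-side inputs to the five similarity-index fields:

* steric      -- cube of the van der Waals radius (volume-like, Å³-scale)
* electrostatic -- Gasteiger partial charge (e)
* hydrophobic -- Crippen atomic logP contribution
* donor / acceptor -- boolean flags from substructure rules
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors
from rdkit.Chem.Crippen import rdMolDescriptors as _rdMD

__all__ = [
    "Molecule3D",
    "MinimizationSettings",
    "parse_structure",
    "molar_mass",
    "embed_and_minimize",
    "assign_field_params",
    "read_smiles_file",
    "write_sdf",
]

# H-bond donor: O-H, N-H, S-H.  Acceptor: N or O with a lone pair that is not
# a positively charged nitrogen; the common SMARTS used by descriptor packages.
_DONOR_SMARTS = Chem.MolFromSmarts("[$([O;H1]),$([N;!H0]),$([S;H1])]")
_ACCEPTOR_SMARTS = Chem.MolFromSmarts(
    "[$([O;X1,X2;!$(O=N-*)]),$([N;X1,X2,X3;!$([N+]);!$(N=O);!$(N-O)])]"
)


@dataclass
class MinimizationSettings:
    """Force-field minimization controls.

    convergence : energy tolerance in kcal/mol between iterations.
    max_iterations : hard cap on minimizer steps.
    random_seed : seed for the distance-geometry embedding.
    """

    convergence: float = 0.005
    max_iterations: int = 10_000
    random_seed: int = 42

    def __post_init__(self) -> None:
        if self.convergence <= 0:
            raise ValueError("convergence must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class Molecule3D:
    """A molecule with coordinates and per-atom field parameters.

    ``coords`` is ``None`` until :func:`embed_and_minimize` has run; the
    per-atom parameter arrays are ``None`` until :func:`assign_field_params`.
    ``rdkit_mol`` keeps the underlying RDKit molecule (with explicit
    hydrogens once embedded) for chemistry-aware operations.
    """

    id: str
    symbols: list[str]
    coords: np.ndarray | None = None
    partial_charges: np.ndarray | None = None
    steric_param: np.ndarray | None = None
    hydrophobic_param: np.ndarray | None = None
    donor_flag: np.ndarray | None = None
    acceptor_flag: np.ndarray | None = None
    formal_charge: int = 0
    rdkit_mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def validate(self) -> None:
        """Check the container invariants; raise ``ValueError`` on violation."""
        n = self.n_atoms
        if self.coords is not None:
            if self.coords.shape != (n, 3):
                raise ValueError(f"{self.id}: coords shape {self.coords.shape} != ({n}, 3)")
            if not np.all(np.isfinite(self.coords)):
                raise ValueError(f"{self.id}: non-finite coordinates")
        for name in ("partial_charges", "steric_param", "hydrophobic_param",
                     "donor_flag", "acceptor_flag"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{self.id}: {name} has {len(arr)} entries for {n} atoms")
        if self.partial_charges is not None:
            if abs(float(self.partial_charges.sum()) - self.formal_charge) > 1e-3:
                raise ValueError(f"{self.id}: charge sum != formal charge")

    def copy(self) -> "Molecule3D":
        new = replace(self)
        for name in ("coords", "partial_charges", "steric_param",
                     "hydrophobic_param", "donor_flag", "acceptor_flag"):
            arr = getattr(new, name)
            if arr is not None:
                setattr(new, name, arr.copy())
        if new.rdkit_mol is not None:
            new.rdkit_mol = Chem.Mol(new.rdkit_mol)
        return new


def parse_structure(text: str, id: str) -> Molecule3D:
    """Parse a SMILES string or a MOL/SDF V2000 block into a molecule.

    The atom order is the order RDKit assigns for the given input text, which
    is deterministic for identical input.  Coordinates are left unset for
    SMILES input; MOL-block coordinates are kept only if non-degenerate 3D.
    """
    if not isinstance(text, str) or not text.strip():
        raise ValueError(f"{id}: empty structure text")
    is_block = "\n" in text and ("V2000" in text or "V3000" in text)
    if is_block:
        mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=False)
    else:
        mol = Chem.MolFromSmiles(text, sanitize=True)
    if mol is None:
        kind = "MOL block" if is_block else "SMILES"
        raise ValueError(f"{id}: unparsable {kind}: {text.splitlines()[0][:80]!r}")
    coords = None
    if is_block and mol.GetNumConformers():
        xyz = mol.GetConformer().GetPositions()
        if np.abs(xyz[:, 2]).max() > 1e-6:  # only keep genuine 3D coordinates
            coords = np.asarray(xyz, dtype=float)
    return Molecule3D(
        id=id,
        symbols=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=coords,
        formal_charge=Chem.GetFormalCharge(mol),
        rdkit_mol=mol,
    )


def molar_mass(mol: Molecule3D) -> float:
    """Molecular weight in g/mol from standard atomic weights.

    Implicit hydrogens are counted.  This is the M entering the char-residue
    formula, so it must reflect the full molecular formula.
    """
    if mol.rdkit_mol is None:
        raise ValueError(f"{mol.id}: no parsed structure")
    return float(Descriptors.MolWt(mol.rdkit_mol))


def embed_and_minimize(
    mol: Molecule3D, settings: MinimizationSettings | None = None
) -> Molecule3D:
    """Generate one low-energy 3D conformer.

    Hydrogens are made explicit, a distance-geometry (ETKDG) embedding is
    produced from ``settings.random_seed``, and the geometry is relaxed with
    MMFF94 (UFF fallback for atoms outside MMFF coverage) until the energy
    change per step falls below ``settings.convergence`` or
    ``settings.max_iterations`` is reached.  Identical seed => identical
    coordinates.  Returns a new molecule; the input is untouched.
    """
    settings = settings or MinimizationSettings()
    if mol.rdkit_mol is None:
        raise ValueError(f"{mol.id}: no parsed structure")
    m = Chem.AddHs(Chem.Mol(mol.rdkit_mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(settings.random_seed)
    params.enforceChirality = True
    if AllChem.EmbedMolecule(m, params) != 0:
        raise ValueError(f"{mol.id}: 3D embedding failed")

    ff = None
    if AllChem.MMFFHasAllMoleculeParams(m):
        props = AllChem.MMFFGetMoleculeProperties(m)
        ff = AllChem.MMFFGetMoleculeForceField(m, props)
    if ff is None:
        ff = AllChem.UFFGetMoleculeForceField(m)
    e0 = ff.CalcEnergy()
    ff.Minimize(maxIts=int(settings.max_iterations),
                energyTol=float(settings.convergence))
    e1 = ff.CalcEnergy()
    if e1 > e0 + 1e-6:
        raise RuntimeError(f"{mol.id}: minimization increased energy")

    out = Molecule3D(
        id=mol.id,
        symbols=[a.GetSymbol() for a in m.GetAtoms()],
        coords=np.asarray(m.GetConformer().GetPositions(), dtype=float),
        formal_charge=Chem.GetFormalCharge(m),
        rdkit_mol=m,
    )
    out.energy_initial = float(e0)  # type: ignore[attr-defined]
    out.energy_minimized = float(e1)  # type: ignore[attr-defined]
    return out


def assign_field_params(mol: Molecule3D) -> Molecule3D:
    """Populate partial charges and the per-atom field parameter arrays.

    Charges are iterative Gasteiger electronegativity-equalization charges;
    steric parameters are r_vdw**3; hydrophobic parameters are Crippen atomic
    logP contributions; donor/acceptor flags come from substructure rules.
    """
    if mol.rdkit_mol is None:
        raise ValueError(f"{mol.id}: no parsed structure")
    m = Chem.Mol(mol.rdkit_mol)
    pt = Chem.GetPeriodicTable()
    for atom in m.GetAtoms():
        if pt.GetRvdw(atom.GetAtomicNum()) <= 0:
            raise ValueError(
                f"{mol.id}: no van der Waals radius for element {atom.GetSymbol()}"
            )
    AllChem.ComputeGasteigerCharges(m, nIter=50, throwOnParamFailure=True)
    charges = np.array(
        [float(a.GetDoubleProp("_GasteigerCharge")) for a in m.GetAtoms()]
    )
    steric = np.array([pt.GetRvdw(a.GetAtomicNum()) ** 3 for a in m.GetAtoms()])
    contribs = _rdMD._CalcCrippenContribs(m)
    hydrophobic = np.array([c[0] for c in contribs])
    donors = np.zeros(m.GetNumAtoms(), dtype=bool)
    for (i,) in m.GetSubstructMatches(_DONOR_SMARTS):
        donors[i] = True
    acceptors = np.zeros(m.GetNumAtoms(), dtype=bool)
    for (i,) in m.GetSubstructMatches(_ACCEPTOR_SMARTS):
        acceptors[i] = True

    out = mol.copy()
    out.rdkit_mol = m
    out.partial_charges = charges
    out.steric_param = steric
    out.hydrophobic_param = hydrophobic
    out.donor_flag = donors
    out.acceptor_flag = acceptors
    out.validate()
    return out


def prepare(smiles: str, id: str,
            settings: MinimizationSettings | None = None) -> Molecule3D:
    """Convenience: parse, embed/minimize, and assign field parameters."""
    return assign_field_params(embed_and_minimize(parse_structure(smiles, id), settings))


def read_smiles_file(path) -> list[Molecule3D]:
    """Read a ``SMILES<TAB>id`` file (one molecule per line, '#' comments)."""
    mols = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'SMILES<TAB>id'")
            mols.append(parse_structure(parts[0], parts[1]))
    return mols


def write_sdf(mols: list[Molecule3D], path) -> None:
    """Write molecules to SDF, attaching computed per-atom parameters as data fields."""
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            if mol.rdkit_mol is None:
                raise ValueError(f"{mol.id}: no structure to write")
            m = Chem.Mol(mol.rdkit_mol)
            m.SetProp("_Name", mol.id)
            for name in ("partial_charges", "steric_param", "hydrophobic_param"):
                arr = getattr(mol, name)
                if arr is not None:
                    m.SetProp(name, " ".join(f"{v:.6f}" for v in arr))
            for name in ("donor_flag", "acceptor_flag"):
                arr = getattr(mol, name)
                if arr is not None:
                    m.SetProp(name, " ".join(str(int(v)) for v in arr))
            writer.write(m)
    finally:
        writer.close()
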