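"""Empirical limited-oxygen-index (LOI) estimation for halogen-free molecules.

The flammability of a halogen-free organic is correlated with the char
residue CR it leaves at 850 °C:

    LOI = 17.5 + 0.4 * CR
    CR  = 1200 * sum_i(CFT_i) / M

where CFT_i is the char-forming contribution of the i-th functional group and
M the molecular weight in g/mol.  For phthalic acid esters the benzene-1,2-
diester (phthalate) moiety contributes CFT = 2 and every other halogen-free
group contributes 0, so LOI is an affine function of 1/M across the family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml
from rdkit import Chem

from .chem_core import Molecule3D, molar_mass

__all__ = ["CFTTable", "FlammabilityResult", "char_residue", "loi", "loi_from_molecule"]

#: benzene ring carrying two ester groups in ortho arrangement
PHTHALATE_SMARTS = "[#6](=O)(O[#6])-c1ccccc1-[#6](=O)O[#6]"

#: the char-forming contribution of the phthalate moiety
PHTHALATE_CFT = 2.0


@dataclass
class CFTTable:
    """Functional-group char-formation contributions.

    ``entries`` maps SMARTS patterns to CFT values; each pattern is counted
    once per molecule (presence, not match multiplicity), matching how the
    phthalate moiety enters the correlation.  ``default_total`` short-circuits
    matching with a fixed sum for a whole molecule class.
    """

    entries: dict[str, float] = field(
        default_factory=lambda: {PHTHALATE_SMARTS: PHTHALATE_CFT}
    )
    default_total: float | None = None

    def __post_init__(self) -> None:
        for patt, value in self.entries.items():
            if value < 0:
                raise ValueError(f"CFT value for {patt!r} must be >= 0")
            if Chem.MolFromSmarts(patt) is None:
                raise ValueError(f"invalid SMARTS pattern: {patt!r}")

    def total(self, mol: Molecule3D) -> float:
        """Sum of CFT contributions resolvable for ``mol``."""
        if self.default_total is not None:
            return float(self.default_total)
        if mol.rdkit_mol is None:
            raise ValueError(f"{mol.id}: no parsed structure")
        total = 0.0
        for patt, value in self.entries.items():
            if mol.rdkit_mol.HasSubstructMatch(Chem.MolFromSmarts(patt)):
                total += value
        return total

    @classmethod
    def from_yaml(cls, path) -> "CFTTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(entries={str(k): float(v) for k, v in raw.get("entries", {}).items()},
                   default_total=raw.get("default_total"))


@dataclass(frozen=True)
class FlammabilityResult:
    CR: float
    LOI: float

    @property
    def LOI_rounded(self) -> float:
        return round(self.LOI, 2)


def char_residue(mol: Molecule3D, cft: CFTTable | None = None) -> float:
    """CR = 1200 * sum(CFT_i) / M for one molecule."""
    cft = cft or CFTTable()
    M = molar_mass(mol)
    if M == 0:
        raise ValueError(f"{mol.id}: zero molar mass")
    return 1200.0 * cft.total(mol) / M


def loi(CR: float) -> float:
    """LOI (%) from the char residue; raw value, round at presentation time."""
    if CR < 0:
        raise ValueError("char residue must be >= 0")
    return 17.5 + 0.4 * CR


def loi_from_molecule(mol: Molecule3D, cft: CFTTable | None = None) -> FlammabilityResult:
    CR = char_residue(mol, cft)
    return FlammabilityResult(CR=CR, LOI=loi(CR))
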