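"""Substituent enumeration on parent plasticizers and multi-criterion screening.

Derivatives are produced by replacing one hydrogen at a named modification
site (a terminal side-chain carbon of the parent) with a substituent
fragment, singly or at both sites.  Candidate records carry the predicted
effect endpoints and their percent changes against the parent; screening
applies the flame-retardancy and eco-friendliness rules (improvement in all
four effects, a minimum LOI gain, the bioaccumulation cap on logBCF, the
semi-volatility band on logKOA, and a positive vibrational frequency where
that column is supplied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_core import Molecule3D, parse_structure

__all__ = ["SubstitutionPlan", "DerivativeRecord", "ScreenRules",
           "enumerate_derivatives", "evaluate_derivatives", "screen"]

#: percent-change direction that counts as improvement, per endpoint
ENDPOINT_DIRECTIONS = {
    "Z": "decrease",
    "LOI": "increase",
    "logLC50": "increase",
    "logBCF": "decrease",
}


@dataclass
class SubstitutionPlan:
    """Enumeration request: parent, sites, substituents, single/double mode.

    ``sites`` maps site labels ('1', '2') to heavy-atom indices of the
    parsed parent; each must carry at least one hydrogen.  ``groups`` maps
    group labels (e.g. 'NO2') to fragment SMILES with exactly one attachment
    point written as ``[*]``.
    """

    parent_id: str
    parent_smiles: str
    sites: dict[str, int]
    groups: dict[str, str]
    mode: str = "single"  # single | double | both

    def __post_init__(self) -> None:
        if len(set(self.sites.values())) != len(self.sites):
            raise ValueError("site atom indices must be distinct")
        if self.mode not in ("single", "double", "both"):
            raise ValueError(f"mode must be single, double or both; got {self.mode!r}")
        for label, frag in self.groups.items():
            m = Chem.MolFromSmiles(frag)
            if m is None:
                raise ValueError(f"group {label!r}: unparsable fragment {frag!r}")
            n_attach = sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == 0)
            if n_attach != 1:
                raise ValueError(
                    f"group {label!r}: fragment must have exactly one attachment "
                    f"point, found {n_attach}"
                )


@dataclass
class DerivativeRecord:
    """One candidate derivative with predictions and percent changes."""

    id: str
    parent: str
    structure: Molecule3D | None = None
    values: dict[str, float] = field(default_factory=dict)
    changes_pct: dict[str, float] = field(default_factory=dict)
    error: str | None = None


@dataclass
class ScreenRules:
    """Pass/fail rules for flame-retardant, eco-friendly candidates."""

    require_z_decrease: bool = True
    require_loi_increase: bool = True
    require_lc50_increase: bool = True
    require_bcf_decrease: bool = True
    loi_improvement_threshold_pct: float = 5.0
    bcf_cap: float = 3.30
    koa_band: tuple[float, float] = (6.5, 10.0)
    require_positive_freq: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.koa_band
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("koa_band must be a finite (lower, upper) with lower < upper")
        if not np.isfinite(self.bcf_cap) or not np.isfinite(self.loi_improvement_threshold_pct):
            raise ValueError("thresholds must be finite")


def _attach(parent: Chem.Mol, site_idx: int, fragment_smiles: str) -> Chem.Mol:
    """Replace one implicit hydrogen at ``site_idx`` with the fragment."""
    frag = Chem.MolFromSmiles(fragment_smiles)
    combined = Chem.RWMol(Chem.CombineMols(parent, frag))
    offset = parent.GetNumAtoms()
    star = next(a.GetIdx() for a in combined.GetAtoms()
                if a.GetIdx() >= offset and a.GetAtomicNum() == 0)
    neighbor = combined.GetAtomWithIdx(star).GetNeighbors()[0].GetIdx()
    site = combined.GetAtomWithIdx(site_idx)
    if site.GetTotalNumHs() < 1:
        raise ValueError(f"site atom {site_idx} has no hydrogen to replace")
    site.SetNumExplicitHs(site.GetTotalNumHs() - 1)
    site.SetNoImplicit(True)
    combined.AddBond(site_idx, neighbor, Chem.BondType.SINGLE)
    combined.RemoveAtom(star)
    out = combined.GetMol()
    Chem.SanitizeMol(out)
    return out


def enumerate_derivatives(plan: SubstitutionPlan) -> list[DerivativeRecord]:
    """All requested (site, group) products, canonically named parent-site-group.

    Single mode yields one product per site and group; double mode one per
    ordered (site1 group, site2 group) pair.  A valence failure on one
    product is recorded on its record (``error``) and enumeration continues.
    """
    parent = parse_structure(plan.parent_smiles, plan.parent_id)
    records: list[DerivativeRecord] = []

    def build(name: str, attachments: list[tuple[int, str]]) -> DerivativeRecord:
        try:
            mol = Chem.Mol(parent.rdkit_mol)
            for site_idx, frag in attachments:
                mol = _attach(mol, site_idx, frag)
            smi = Chem.MolToSmiles(mol)
            return DerivativeRecord(id=name, parent=plan.parent_id,
                                    structure=parse_structure(smi, name))
        except Exception as exc:  # per-product failure, others continue
            return DerivativeRecord(id=name, parent=plan.parent_id, error=str(exc))

    site_labels = sorted(plan.sites)
    if plan.mode in ("single", "both"):
        for s in site_labels:
            for g, frag in plan.groups.items():
                records.append(build(f"{plan.parent_id}-{s}-{g}",
                                     [(plan.sites[s], frag)]))
    if plan.mode in ("double", "both"):
        if len(site_labels) < 2:
            raise ValueError("double mode needs two sites")
        s1, s2 = site_labels[0], site_labels[1]
        for g1, f1 in plan.groups.items():
            for g2, f2 in plan.groups.items():
                records.append(
                    build(f"{plan.parent_id}-{s1}-{g1}-{s2}-{g2}",
                          [(plan.sites[s1], f1), (plan.sites[s2], f2)])
                )
    return records


def evaluate_derivatives(
    derivatives: list[DerivativeRecord],
    models: dict[str, Callable[[Molecule3D], float]],
    parent_values: dict[str, float],
) -> pd.DataFrame:
    """Predict every endpoint for each derivative and compute percent changes.

    ``models`` maps endpoint name -> predictor callable; ``parent_values``
    holds the parent's value per endpoint.  Percent changes follow the
    improvement sign conventions: for a 'decrease' endpoint the change column
    is positive when the value fell, for an 'increase' endpoint positive when
    it rose.
    """
    missing = [e for e in parent_values if e not in models]
    if missing:
        raise KeyError(f"no fitted model for endpoint(s): {missing}")
    rows = []
    for rec in derivatives:
        if rec.error is not None:
            continue
        row: dict[str, object] = {"id": rec.id, "parent": rec.parent}
        for endpoint, predictor in models.items():
            value = float(predictor(rec.structure))
            rec.values[endpoint] = value
            row[endpoint] = round(value, 3)
            parent = parent_values[endpoint]
            direction = ENDPOINT_DIRECTIONS.get(endpoint, "increase")
            delta = (parent - value) if direction == "decrease" else (value - parent)
            pct = delta / abs(parent) * 100.0
            rec.changes_pct[endpoint] = pct
            suffix = "decrease_pct" if direction == "decrease" else "increase_pct"
            row[f"{endpoint}_{suffix}"] = round(pct, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def screen(records: pd.DataFrame, rules: ScreenRules | None = None) -> pd.DataFrame:
    """Apply the screening rules; returns records plus per-rule flags.

    ``records`` needs the percent-change columns (Z_decrease_pct,
    LOI_increase_pct, logLC50_increase_pct, logBCF_decrease_pct) and the raw
    logBCF column; logKOA and freq columns are optional — their rules are
    skipped with a warning when absent.  The returned frame adds one boolean
    column per applied rule and a ``passes`` column that is their AND.
    """
    rules = rules or ScreenRules()
    out = records.copy()
    checks: dict[str, pd.Series] = {}
    if rules.require_z_decrease:
        checks["rule_z_decreased"] = out["Z_decrease_pct"] > 0
    if rules.require_loi_increase:
        checks["rule_loi_increased"] = out["LOI_increase_pct"] > 0
    if rules.require_lc50_increase:
        checks["rule_lc50_increased"] = out["logLC50_increase_pct"] > 0
    if rules.require_bcf_decrease:
        checks["rule_bcf_decreased"] = out["logBCF_decrease_pct"] > 0
    checks["rule_loi_improvement"] = out["LOI_increase_pct"] > rules.loi_improvement_threshold_pct
    if "logBCF" in out.columns:
        checks["rule_bcf_cap"] = out["logBCF"] < rules.bcf_cap
    if "logKOA" in out.columns:
        lo, hi = rules.koa_band
        checks["rule_koa_band"] = (out["logKOA"] >= lo) & (out["logKOA"] <= hi)
    if rules.require_positive_freq:
        if "freq" in out.columns:
            checks["rule_freq_positive"] = out["freq"] > 0
        else:
            warnings.warn("freq column absent; stability rule skipped", stacklevel=2)
    for name, flag in checks.items():
        out[name] = flag.fillna(False)
    out["passes"] = np.logical_and.reduce([out[name].to_numpy() for name in checks])
    return out
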