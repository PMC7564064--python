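"""Modified-group property coupling and group-wise effect analysis.

A substituent's strength is summarized by coupling its volume gain and its
hydrophobicity (logP) gain, weighted by the steric and hydrophobic field
contribution fractions of the fitted multi-effect model:

    coupling % = w_steric * dVol% + w_hydrophobic * dlogP%

with defaults w_steric = 0.229 and w_hydrophobic = 0.449 (the field
fractions as decimals, used unnormalized).  Volume baselines are the
hydrogen reference (1.0 per site, 2.0 for double substitution); the logP
baseline is the parent molecule.  Group-level behaviour is summarized by
averaging, over all derivatives carrying the group, the comprehensive-effect
reduction, the coupling value, and the three single-effect improvements,
plus the 40/30/30-weighted combination of the latter; coupling strength and
achieved improvement are then compared by Pearson correlation against
two-sided critical values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["percent_increase", "coupling_value", "coupling_table",
           "group_summaries", "pearson_r", "critical_r"]

W_STERIC = 0.229
W_HYDROPHOBIC = 0.449

#: default weights of the flammability/biotoxicity/enrichment improvements
EFFECT_WEIGHTS = (0.4, 0.3, 0.3)


def percent_increase(value: float, baseline: float) -> float:
    """(value - baseline) / baseline * 100."""
    if baseline == 0:
        raise ValueError("zero baseline")
    return (value - baseline) / baseline * 100.0


def coupling_value(vol_increase_pct: float, logp_increase_pct: float,
                   w_steric: float = W_STERIC,
                   w_hydrophobic: float = W_HYDROPHOBIC) -> float:
    """Weighted (unnormalized) sum of the volume and hydrophobicity gains."""
    return w_steric * vol_increase_pct + w_hydrophobic * logp_increase_pct


def coupling_table(
    raw: pd.DataFrame,
    volumes: dict[str, float],
    w_steric: float = W_STERIC,
    w_hydrophobic: float = W_HYDROPHOBIC,
    h_volume: float = 1.0,
) -> pd.DataFrame:
    """Per-derivative coupling records from raw inputs.

    ``raw`` needs columns id, parent, site1_group, site2_group, logP; parent
    rows (empty parent field) supply the logP baselines.  ``volumes`` maps
    group label -> group volume on the hydrogen-=-1 scale.  For a single
    substitution the coupling uses that site's volume gain; for a double
    substitution the combined volume (baseline ``2 * h_volume``).
    """
    parents = raw[raw["parent"].isna() | (raw["parent"] == "")]
    parent_logp = dict(zip(parents["id"], parents["logP"].astype(float)))
    rows = []
    for _, r in raw.iterrows():
        if pd.isna(r["parent"]) or r["parent"] == "":
            continue
        if r["parent"] not in parent_logp:
            raise KeyError(f"{r['id']}: no parent logP baseline for {r['parent']!r}")
        g1 = r.get("site1_group")
        g2 = r.get("site2_group")
        g1 = None if (pd.isna(g1) or g1 == "") else str(g1)
        g2 = None if (pd.isna(g2) or g2 == "") else str(g2)
        if g1 is None and g2 is None:
            raise ValueError(f"{r['id']}: no substituent groups given")
        for g in (g1, g2):
            if g is not None and g not in volumes:
                raise KeyError(f"{r['id']}: no volume for group {g!r}")
        if g1 is not None and g2 is not None:
            vol = volumes[g1] + volumes[g2]
            vol_inc = percent_increase(vol, 2.0 * h_volume)
        else:
            vol = volumes[g1 or g2]
            vol_inc = percent_increase(vol, h_volume)
        logp_inc = percent_increase(float(r["logP"]), parent_logp[r["parent"]])
        rows.append({
            "id": r["id"],
            "parent": r["parent"],
            "site1_group": g1,
            "site2_group": g2,
            "volume": vol,
            "volume_increase_pct": vol_inc,
            "logP": float(r["logP"]),
            "logP_increase_pct": logp_inc,
            "coupling_value": coupling_value(vol_inc, logp_inc, w_steric, w_hydrophobic),
        })
    return pd.DataFrame(rows)


def group_summaries(
    coupling_df: pd.DataFrame,
    effect_table: pd.DataFrame,
    effect_weights: tuple[float, float, float] = EFFECT_WEIGHTS,
) -> pd.DataFrame:
    """Group-wise means of effect improvements and coupling strength.

    A derivative contributes to the summary of every group it carries
    (site 1 and/or site 2).  Only derivatives present in ``effect_table``
    (indexed or keyed by id, with Z_decrease_pct / LOI_increase_pct /
    logLC50_increase_pct / logBCF_decrease_pct columns) enter the means;
    groups left with no members are omitted with a warning.  The weighted
    comprehensive effect combines the flammability, biotoxicity, and
    enrichment improvements with ``effect_weights``.
    """
    eff = effect_table.set_index("id") if "id" in effect_table.columns else effect_table
    w_f, w_b, w_c = effect_weights
    groups: dict[str, list[str]] = {}
    for _, r in coupling_df.iterrows():
        for g in (r["site1_group"], r["site2_group"]):
            if g is not None and not pd.isna(g):
                groups.setdefault(g, [])
                if r["id"] not in groups[g]:
                    groups[g].append(r["id"])
    cv = coupling_df.set_index("id")["coupling_value"]
    rows = []
    for g, members in groups.items():
        present = [m for m in members if m in eff.index]
        if not present:
            warnings.warn(f"group {g!r} has no members in the effect table; omitted",
                          stacklevel=2)
            continue
        comp = float(eff.loc[present, "Z_decrease_pct"].mean())
        flame = float(eff.loc[present, "LOI_increase_pct"].mean())
        biotox = float(eff.loc[present, "logLC50_increase_pct"].mean())
        conc = float(eff.loc[present, "logBCF_decrease_pct"].mean())
        rows.append({
            "group": g,
            "n_members": len(present),
            "comprehensive_effect_pct": comp,
            "group_properties_pct": float(cv.loc[present].mean()),
            "flame_retardancy_pct": flame,
            "biotoxicity_pct": biotox,
            "concentration_pct": conc,
            "weighted_comprehensive_effect_pct": w_f * flame + w_b * biotox + w_c * conc,
        })
    return pd.DataFrame(rows)


def critical_r(n: int, alpha: float) -> float:
    """Two-sided critical Pearson correlation for sample size n."""
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    t = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(t**2 + df))


def pearson_r(x, y) -> dict[str, float | bool]:
    """Sample Pearson correlation with significance flags at P=0.05 and P=0.01."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(stats.pearsonr(x, y).statistic)
    c05 = critical_r(x.size, 0.05)
    c01 = critical_r(x.size, 0.01)
    return {"R": r, "critical_p05": c05, "critical_p01": c01,
            "significant_p05": abs(r) > c05, "significant_p01": abs(r) > c01}
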