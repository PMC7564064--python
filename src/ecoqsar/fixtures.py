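"""Packaged reference tables and their loaders.

The package ships the plasticizer study tables as CSV resources: the 17-PAE
property table (with SMILES and train/test split), the derivative effect
table, the eco-friendliness table (logHL, logKOA, Freq, energy gap), the
group coupling inputs, the group summary reference, and the substituent
volume/fragment lookup.  Loaders verify a pinned SHA-256 checksum so silent
edits fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd
import yaml

__all__ = ["load_fixture", "fixture_names", "load_sites", "group_volumes",
           "group_fragments"]

_FILES = {
    "table1": "table1.csv",
    "table7": "table7.csv",
    "table8": "table8.csv",
    "table9": "table9.csv",
    "table10": "table10.csv",
    "groups": "groups.csv",
}


def fixture_names() -> list[str]:
    return sorted(_FILES)


def _data_path(filename: str):
    return resources.files("ecoqsar.data").joinpath(filename)


def _checksums() -> dict[str, str]:
    with _data_path("checksums.json").open() as fh:
        return json.load(fh)


def load_fixture(name: str, verify: bool = True) -> pd.DataFrame:
    """Load a packaged table by name; checksum-verified by default."""
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")
    path = _data_path(_FILES[name])
    raw = path.read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        expected = _checksums()[_FILES[name]]
        if digest != expected:
            raise ValueError(
                f"fixture {name!r} checksum mismatch: {digest} != {expected}"
            )
    with path.open() as fh:
        return pd.read_csv(fh)


def load_sites() -> dict:
    """Modification-site definitions per parent (label -> heavy-atom index)."""
    with _data_path("sites.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {
        parent: {"smiles": entry["smiles"],
                 "sites": {str(k): int(v) for k, v in entry["sites"].items()}}
        for parent, entry in raw.items()
    }


def group_volumes() -> dict[str, float]:
    """Substituent volume lookup on the hydrogen-=-1 scale."""
    df = load_fixture("groups")
    return dict(zip(df["group"], df["volume"].astype(float)))


def group_fragments() -> dict[str, str]:
    """Substituent fragment SMILES (one [*] attachment point each)."""
    df = load_fixture("groups")
    return {g: s for g, s in zip(df["group"], df["fragment_smiles"]) if g != "H"}
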