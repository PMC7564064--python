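"""Ideal-point multi-criteria scoring of molecular effect indices.

Raw indices with different units (LOI %, fish LC50 mg/L, logBCF, ...) are
first made dimensionless by min-max normalization over the molecule set:

    positive index (larger is better):  C = (X - min X) / (max X - min X)
    inverse  index (smaller is better): C = (max X - X) / (max X - min X)

so every normalized column runs 0..1 with 1 the preferred end.  Each molecule
is then scored by its weighted distance from the ideal point C* (all ones by
default):

    euclidean (default):  Z = sqrt( sum_j  lambda_j * (C_j - C*_j)^2 )
    manhattan           :  Z =       sum_j  lambda_j * |C_j - C*_j|

Smaller Z means closer to the ideal.  The euclidean form is the default
because it is the one consistent with the reference comprehensive-evaluation
values this package reproduces; the manhattan form is kept as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["IdealPointConfig", "ScoreResult", "normalize", "ideal_point_score",
           "rank_by_score", "score_table"]

#: default index layout: flammability (LOI), biotoxicity (raw LC50),
#: enrichment (logBCF, inverse), weighted 40/30/30
DEFAULT_INDICES = ("LOI", "LC50", "logBCF")
DEFAULT_DIRECTIONS = ("positive", "positive", "inverse")
DEFAULT_WEIGHTS = (0.4, 0.3, 0.3)


@dataclass
class IdealPointConfig:
    """Index directions, weights, ideal point, and distance metric."""

    indices: tuple[str, ...] = DEFAULT_INDICES
    directions: tuple[str, ...] = DEFAULT_DIRECTIONS
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    ideal_point: tuple[float, ...] | float = 1.0
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if len(self.indices) != len(self.directions) or len(self.indices) != len(self.weights):
            raise ValueError("indices, directions and weights must have equal length")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be >= 0")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.weights)}")
        bad = [d for d in self.directions if d not in ("positive", "inverse")]
        if bad:
            raise ValueError(f"directions must be 'positive' or 'inverse', got {bad}")
        if self.metric not in ("euclidean", "manhattan"):
            raise ValueError(f"metric must be 'euclidean' or 'manhattan', got {self.metric!r}")

    @property
    def ideal_vector(self) -> np.ndarray:
        c = self.ideal_point
        if np.isscalar(c):
            return np.full(len(self.indices), float(c))
        c = np.asarray(c, dtype=float)
        if c.shape != (len(self.indices),):
            raise ValueError("ideal_point length must match indices")
        return c


@dataclass
class ScoreResult:
    normalized: pd.DataFrame  # molecules x indices, values in [0, 1]
    Z: pd.Series  # comprehensive value per molecule (smaller = better)
    config: IdealPointConfig = field(repr=False, default_factory=IdealPointConfig)


def normalize(table: pd.DataFrame, config: IdealPointConfig) -> pd.DataFrame:
    """Min-max normalize the scored columns; inverse indices are flipped."""
    out = {}
    for name, direction in zip(config.indices, config.directions):
        if name not in table.columns:
            raise KeyError(f"column {name!r} missing from the property table")
        x = table[name].astype(float)
        if x.isna().any():
            raise ValueError(f"column {name!r} contains missing values")
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError(f"degenerate (constant) index column: {name!r}")
        if direction == "positive":
            out[name] = (x - lo) / (hi - lo)
        else:
            out[name] = (hi - x) / (hi - lo)
    return pd.DataFrame(out, index=table.index)


def ideal_point_score(C: pd.DataFrame, config: IdealPointConfig) -> pd.Series:
    """Weighted distance of each normalized row from the ideal point."""
    if list(C.columns) != list(config.indices):
        raise ValueError("normalized matrix columns do not match config.indices")
    lam = np.asarray(config.weights, dtype=float)
    dev = C.to_numpy(dtype=float) - config.ideal_vector
    if config.metric == "euclidean":
        z = np.sqrt((lam * dev**2).sum(axis=1))
    else:
        z = (lam * np.abs(dev)).sum(axis=1)
    return pd.Series(z, index=C.index, name="Z")


def score_table(table: pd.DataFrame, config: IdealPointConfig | None = None) -> ScoreResult:
    """Normalize and score a property table in one step."""
    config = config or IdealPointConfig()
    C = normalize(table, config)
    return ScoreResult(normalized=C, Z=ideal_point_score(C, config), config=config)


def rank_by_score(result: ScoreResult) -> pd.Series:
    """Molecules ordered by ascending Z (best first); ties broken by id."""
    df = result.Z.rename_axis("id").reset_index()
    df = df.sort_values(["Z", "id"], kind="stable")
    return pd.Series(df["Z"].to_numpy(), index=df["id"], name="Z")
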