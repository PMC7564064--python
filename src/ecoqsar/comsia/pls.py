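"""Partial least squares (NIPALS) regression with LOO cross-validation.

The descriptor matrix of a 3D-QSAR problem has thousands of collinear
lattice columns and a handful of molecules, the classic PLS regime.  The
single-response NIPALS algorithm is implemented directly (deflation of X
against successive latent components); an external reference implementation
is used only as a cross-check in the test suite.

Near-constant lattice columns carry no information and are dropped before
fitting.  The range threshold below which a column is discarded is expressed
as a fraction of an energy-style cutoff (default cutoff 125.4, default
fraction 0, i.e. only exactly-degenerate columns go); both knobs are config
values and the filtering is documented rather than load-bearing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "ModelStats", "pls_fit", "loo_q2", "model_stats",
           "field_fractions", "choose_n_components", "COLUMN_FILTER_CUTOFF"]

#: energy-style cutoff whose configured fraction sets the column-range filter
COLUMN_FILTER_CUTOFF = 125.4


@dataclass
class PLSModel:
    """A fitted latent-variable regression y ~ X.

    ``coef`` is expressed on the centered, retained columns; ``mask`` maps
    retained columns back into the full descriptor layout.  ``fitted`` holds
    the training predictions.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    mask: np.ndarray  # boolean over the full column set
    x_std: np.ndarray  # stdev of retained columns (for StDev*Coeff maps)
    fitted: np.ndarray
    field_labels: np.ndarray | None = None  # full-layout labels, optional

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] == self.mask.size:
            X = X[:, self.mask]
        elif X.shape[1] != self.mask.sum():
            raise ValueError(
                f"descriptor width {X.shape[1]} matches neither the full layout "
                f"({self.mask.size}) nor the retained columns ({int(self.mask.sum())})"
            )
        return self.y_mean + (X - self.x_mean) @ self.coef

    def to_json(self, path) -> None:
        payload = {
            "format": "ecoqsar-pls/1",
            "n_components": int(self.n_components),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "coef": self.coef.tolist(),
            "mask": self.mask.astype(int).tolist(),
            "x_std": self.x_std.tolist(),
            "fitted": self.fitted.tolist(),
            "field_labels": None if self.field_labels is None else list(map(str, self.field_labels)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "ecoqsar-pls/1":
            raise ValueError(f"{path}: not an ecoqsar PLS model file")
        return cls(
            n_components=payload["n_components"],
            x_mean=np.array(payload["x_mean"]),
            y_mean=payload["y_mean"],
            coef=np.array(payload["coef"]),
            mask=np.array(payload["mask"], dtype=bool),
            x_std=np.array(payload["x_std"]),
            fitted=np.array(payload["fitted"]),
            field_labels=None if payload["field_labels"] is None
            else np.array(payload["field_labels"]),
        )


@dataclass
class ModelStats:
    """Fit and validation statistics of a PLS QSAR model."""

    q2: float | None
    r2: float
    SEE: float
    F: float
    r2_pred: float | None = None
    SEP: float | None = None
    field_contributions: dict[str, float] | None = None

    #: conventional adequacy thresholds for a predictive QSAR model
    Q2_THRESHOLD = 0.5
    R2_THRESHOLD = 0.9
    R2_PRED_THRESHOLD = 0.6

    @property
    def predictive(self) -> bool:
        ok = self.r2 > self.R2_THRESHOLD
        if self.q2 is not None:
            ok = ok and self.q2 > self.Q2_THRESHOLD
        if self.r2_pred is not None:
            ok = ok and self.r2_pred > self.R2_PRED_THRESHOLD
        return ok


def _nipals(Xc: np.ndarray, yc: np.ndarray, n: int) -> np.ndarray:
    """Regression vector of n-component PLS1 on centered data."""
    X = Xc.copy()
    y = yc.copy()
    W, P, Q = [], [], []
    for _ in range(n):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            break  # residual orthogonal to y: no further components
        w /= norm
        t = X @ w
        tt = t @ t
        if tt < 1e-14:
            break
        p = X.T @ t / tt
        q = y @ t / tt
        X = X - np.outer(t, p)
        y = y - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
    if not W:
        return np.zeros(Xc.shape[1])
    W, P, Q = np.array(W).T, np.array(P).T, np.array(Q)
    return W @ np.linalg.solve(P.T @ W, Q)


def _filter_mask(X: np.ndarray, cutoff_fraction: float) -> np.ndarray:
    threshold = max(cutoff_fraction * COLUMN_FILTER_CUTOFF, 0.0)
    rng = X.max(axis=0) - X.min(axis=0)
    mask = rng > max(threshold, 1e-12)
    return mask


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    field_labels: np.ndarray | None = None,
    column_filter_fraction: float = 0.0,
) -> PLSModel:
    """Fit an n-component PLS1 model of y on the descriptor matrix X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m = X.shape[0]
    if m != y.size:
        raise ValueError(f"X has {m} rows but y has {y.size} entries")
    if m < 2:
        raise ValueError("need at least 2 samples")
    mask = _filter_mask(X, column_filter_fraction)
    if not mask.any():
        raise ValueError("column filtering removed every descriptor column")
    Xr = X[:, mask]
    max_n = min(m - 1, Xr.shape[1])
    if not 1 <= n_components <= max_n:
        raise ValueError(
            f"n_components must be in [1, {max_n}] for {m} samples and "
            f"{Xr.shape[1]} retained columns; got {n_components}"
        )
    x_mean = Xr.mean(axis=0)
    y_mean = float(y.mean())
    coef = _nipals(Xr - x_mean, y - y_mean, n_components)
    fitted = y_mean + (Xr - x_mean) @ coef
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        mask=mask,
        x_std=Xr.std(axis=0, ddof=1),
        fitted=fitted,
        field_labels=field_labels,
    )


def loo_q2(X: np.ndarray, y: np.ndarray, n_components: int,
           column_filter_fraction: float = 0.0) -> tuple[float, float]:
    """Leave-one-out q2 and PRESS by refitting with each sample excluded.

    q2 = 1 - PRESS / sum((y - mean(y))^2); each held-out prediction comes
    from a model fitted on the remaining m-1 samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m = X.shape[0]
    if m < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    press = 0.0
    idx = np.arange(m)
    for i in range(m):
        keep = idx != i
        model = pls_fit(X[keep], y[keep], n_components,
                        column_filter_fraction=column_filter_fraction)
        press += float((model.predict(X[i : i + 1])[0] - y[i]) ** 2)
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss, press


def choose_n_components(X: np.ndarray, y: np.ndarray, max_n: int | None = None,
                        column_filter_fraction: float = 0.0) -> tuple[int, float]:
    """Pick n maximizing LOO q2, subject to n <= m - 2."""
    m = np.asarray(y).size
    cap = m - 2
    if max_n is not None:
        cap = min(cap, max_n)
    if cap < 1:
        raise ValueError("too few samples to select components")
    best_n, best_q2 = 1, -np.inf
    for n in range(1, cap + 1):
        q2, _ = loo_q2(X, y, n, column_filter_fraction)
        if q2 > best_q2 + 1e-12:
            best_n, best_q2 = n, q2
    return best_n, best_q2


def model_stats(
    model: PLSModel,
    X: np.ndarray,
    y: np.ndarray,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    q2: float | None = None,
) -> ModelStats:
    """Fit statistics, optionally with external-test validation.

    r2 = 1 - RSS/SS; SEE = sqrt(RSS / (m - n - 1)); F = (r2/n) / ((1-r2)/(m-n-1)).
    For an external test set, r2_pred = 1 - PRESS_test / SD_test with SD_test
    the squared deviations of the test responses about the *training* mean,
    and SEP = sqrt(PRESS_test / m_test).
    """
    y = np.asarray(y, dtype=float).ravel()
    m, n = y.size, model.n_components
    dof = m - n - 1
    if dof <= 0:
        raise ValueError(f"SEE/F undefined: m - n - 1 = {dof} <= 0")
    resid = y - model.predict(X)
    rss = float((resid**2).sum())
    ss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / ss
    see = float(np.sqrt(rss / dof))
    f_stat = (r2 / n) / ((1.0 - r2) / dof) if r2 < 1.0 else np.inf
    r2_pred = sep = None
    if X_test is not None and y_test is not None and len(y_test):
        y_test = np.asarray(y_test, dtype=float).ravel()
        press = float(((y_test - model.predict(X_test)) ** 2).sum())
        sd = float(((y_test - model.y_mean) ** 2).sum())
        r2_pred = 1.0 - press / sd
        sep = float(np.sqrt(press / y_test.size))
    contrib = None
    if model.field_labels is not None:
        contrib = field_fractions(model)
    return ModelStats(q2=q2, r2=r2, SEE=see, F=f_stat,
                      r2_pred=r2_pred, SEP=sep, field_contributions=contrib)


def field_fractions(model: PLSModel,
                    field_order: tuple[str, ...] = ("S", "E", "H", "D", "A")) -> dict[str, float]:
    """Per-field contribution percentages: sum |coef * stdev| within each block.

    Reported in S, E, H, D, A order; the percentages sum to 100.
    """
    if model.field_labels is None:
        raise ValueError("model carries no field labels")
    labels = np.asarray(model.field_labels)[model.mask]
    weight = np.abs(model.coef * model.x_std)
    total = float(weight.sum())
    out = {}
    present = [f for f in field_order if (labels == f).any()]
    if not present:
        present = list(dict.fromkeys(labels))
    for f in present:
        block = float(weight[labels == f].sum())
        out[f] = 100.0 * block / total if total > 0 else 0.0
    return out


def relative_error_pct(predicted: float, observed: float) -> float:
    """(pred - obs) / obs * 100, the sign convention of prediction tables."""
    if observed == 0:
        raise ValueError("observed value is zero")
    return (predicted - observed) / observed * 100.0
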