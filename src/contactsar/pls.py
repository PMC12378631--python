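"""PLS1 regression (NIPALS) linking contact occupancies to potency.

The model projects the ligands x contacts occupancy block X onto latent
components that maximally covary with the response y = pIC50, then exposes
per-contact weights (component directions) and regression coefficients.
Negative coefficients mark contacts whose persistence tracks *lower*
potency, positive ones contacts associated with enhanced activity — the
statistic behind ranked contact-importance bar plots.

NIPALS is implemented here directly so the fit is fully inspectable;
columns of X are mean-centred and, by default, scaled to unit variance
(autoscaling).  Zero-variance columns get scale 1 and necessarily zero
weight.  With as many components as the (centred) predictor rank, PLS1
reproduces the ordinary least-squares fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .occupancy import OccupancyMatrix

__all__ = ["PLSModel", "fit_pls", "contact_weights", "predict"]

_EPS = 1e-12


@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray  # contacts x components, unit-norm columns
    x_loadings: np.ndarray  # contacts x components
    y_loadings: np.ndarray  # components
    x_scores: np.ndarray  # rows x components
    beta_standardized: np.ndarray  # per contact, on the autoscaled X scale
    beta_raw: np.ndarray  # per contact, on the original X scale
    contact_ids: list[str] = field(default_factory=list)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, OccupancyMatrix):
        return np.asarray(X.values, dtype=float), list(X.contact_ids)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be two-dimensional")
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def fit_pls(
    X: Union[OccupancyMatrix, pd.DataFrame, np.ndarray],
    y: Sequence[float],
    n_components: Optional[int] = None,
    scale: bool = True,
) -> PLSModel:
    """Fit a PLS1 model of y on X by NIPALS.

    Columns of X are centred and (if ``scale``) divided by their sample
    standard deviation (ddof=1); y is centred.  Each component extracts a
    unit-norm weight vector proportional to X'y on the deflated block,
    scores t = Xw, loadings p = X't/t't and q = y't/t't, then deflates.
    ``n_components`` defaults to min(2, rows - 1).  A constant y yields an
    all-zero coefficient vector with a warning.
    """
    Xm, contact_ids = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = Xm.shape
    if yv.size != n:
        raise ValueError(f"X has {n} rows but y has {yv.size} entries")
    if n < 2:
        raise ValueError("need at least two observations")
    if n_components is None:
        n_components = min(2, n - 1)
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} outside valid range 1..{min(n - 1, p)}"
        )

    x_mean = Xm.mean(axis=0)
    if scale:
        x_scale = Xm.std(axis=0, ddof=1)
        x_scale[x_scale < _EPS] = 1.0
    else:
        x_scale = np.ones(p)
    Xc = (Xm - x_mean) / x_scale
    y_mean = float(yv.mean())
    yc = yv - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xk, yk = Xc.copy(), yc.copy()
    extracted = 0
    for a in range(n_components):
        w = Xk.T @ yk
        nw = np.linalg.norm(w)
        if nw < _EPS:
            break
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        W[:, a], T[:, a] = w, t
        P[:, a] = Xk.T @ t / tt
        q[a] = float(yk @ t) / tt
        Xk = Xk - np.outer(t, P[:, a])
        yk = yk - q[a] * t
        extracted += 1

    if extracted == 0:
        warnings.warn("response has no variance; all coefficients are zero", stacklevel=2)
        beta_std = np.zeros(p)
    else:
        Wa, Pa, qa = W[:, :extracted], P[:, :extracted], q[:extracted]
        beta_std = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    W, P, T = W[:, : max(extracted, 1)], P[:, : max(extracted, 1)], T[:, : max(extracted, 1)]
    return PLSModel(
        n_components=max(extracted, 1) if extracted else 0,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q[: max(extracted, 1)],
        x_scores=T,
        beta_standardized=beta_std,
        beta_raw=beta_std / x_scale,
        contact_ids=contact_ids,
    )


def contact_weights(
    model: PLSModel,
    component: int = 1,
    ligand_part: Optional[str] = None,
) -> list[tuple[str, float]]:
    """Weights of one component ranked by absolute value, descending.

    ``component`` is 1-based.  ``ligand_part`` optionally restricts the
    list to contacts whose id starts with that ligand-side label (e.g.
    ``"C_COOH"`` for the C-terminal carboxylate subset).
    """
    if not 1 <= component <= model.weights.shape[1]:
        raise ValueError(
            f"component {component} outside 1..{model.weights.shape[1]}"
        )
    w = model.weights[:, component - 1]
    items = list(zip(model.contact_ids, w.tolist()))
    if ligand_part is not None:
        items = [(cid, val) for cid, val in items if cid.split("-")[0] == ligand_part]
    return sorted(items, key=lambda kv: abs(kv[1]), reverse=True)


def predict(
    model: PLSModel, X_new: Union[OccupancyMatrix, pd.DataFrame, np.ndarray]
) -> np.ndarray:
    """Predicted pIC50: y_mean + standardized(X_new) . beta."""
    Xm, ids = _as_matrix(X_new)
    if isinstance(X_new, (OccupancyMatrix, pd.DataFrame)) and ids != model.contact_ids:
        raise ValueError("X_new columns do not match the model's contact_ids")
    if Xm.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {Xm.shape[1]} columns, model expects {model.x_mean.size}"
        )
    Xc = (Xm - model.x_mean) / model.x_scale
    return model.y_mean + Xc @ model.beta_standardized


def coefficients_frame(model: PLSModel) -> pd.DataFrame:
    """Tabulate standardized and raw coefficients per contact."""
    return pd.DataFrame(
        {
            "contact_id": model.contact_ids,
            "beta_standardized": model.beta_standardized,
            "beta_raw": model.beta_raw,
        }
    )


def weights_frame(model: PLSModel) -> pd.DataFrame:
    """Long-format weight table: contact_id, component (1-based), weight."""
    rows = []
    for a in range(model.weights.shape[1]):
        for cid, w in zip(model.contact_ids, model.weights[:, a]):
            rows.append({"contact_id": cid, "component": a + 1, "weight": w})
    return pd.DataFrame(rows)
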