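"""Nested dummy-coded linear models for batch-effect quantification.

Response matrices Y (N ROIs x T time samples) are regressed on indicator designs:

* polarity only (On/Off; 2 columns) — the fit is just the two polarity-mean traces;
* IPL depth, 10 equal-width bins per polarity (20 columns);
* batch (scan field), one predictor per (batch, polarity) with the first batch
  left out as reference (2B columns);
* the combined batch + depth model, in which the batch predictors are first
  orthogonalized against the depth design so that any variance shared between
  depth and batch is ascribed to depth — conservatively treating ambiguous
  variance as biological signal rather than nuisance.

Explained variance is computed per ROI as E.V. = 1 - E[(y - y_hat)^2] / Var[y]
and aggregated as mean with 2 SEM across ROIs.  Although these are sometimes
called "mixed" models in the field, they are plain fixed-effects dummy
regressions fitted by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "DesignMatrixSet",
    "LinearFit",
    "depth_bin_index",
    "build_designs",
    "orthogonalize_batch",
    "fit_ols",
    "explained_variance",
    "explained_variance_summary",
    "compare_models",
]

POLARITY_LEVELS = ("On", "Off")


def depth_bin_index(
    depth: np.ndarray, n_bins: int = 10, depth_range: tuple[float, float] = (-1.0, 2.0)
) -> tuple[np.ndarray, np.ndarray, int]:
    """Equal-width depth-bin index for each ROI.

    ROIs outside ``depth_range`` are clipped to the end bins (with a warning).
    Returns (bin_index, bin_edges, n_clipped).
    """
    depth = np.asarray(depth, dtype=float)
    lo, hi = depth_range
    if not hi > lo:
        raise ConfigError(f"invalid depth range {depth_range}")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(depth, edges[1:-1])
    n_clipped = int(np.sum((depth < lo) | (depth >= hi)))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} ROI(s) outside depth range {depth_range}; clipped to end bins",
            stacklevel=2,
        )
    return idx, edges, n_clipped


@dataclass
class DesignMatrixSet:
    """Dummy-coded predictor matrices for the nested linear models."""

    X_polarity: np.ndarray            # (N, 2)
    X_depth: np.ndarray               # (N, 2 * n_bins)
    X_batch: np.ndarray               # (N, 2 * (n_batch - 1)); reference batch all-zero rows
    X_batch_orth: np.ndarray | None = None
    bin_edges: np.ndarray = field(default_factory=lambda: np.empty(0))
    batch_ids: tuple = ()             # sorted; batch_ids[0] is the reference
    n_bins: int = 10
    empty_depth_cols: tuple[int, ...] = ()

    @property
    def n_encoded_batches(self) -> int:
        return self.X_batch.shape[1] // 2


def build_designs(
    table: pd.DataFrame,
    n_bins: int = 10,
    depth_range: tuple[float, float] = (-1.0, 2.0),
) -> DesignMatrixSet:
    """Build the polarity / depth / batch indicator designs from an ROI table.

    ``table`` needs columns ``polarity`` ('On'/'Off'), ``depth`` (aligned ChAT
    units) and ``batch`` (hashable id).  Depth bins are equal-width over
    ``depth_range`` per polarity; the lexicographically first batch is the
    reference and receives no batch columns.  Empty depth-bin columns are kept
    (all-zero) and flagged.
    """
    for col in ("polarity", "depth", "batch"):
        if col not in table.columns:
            raise ConfigError(f"ROI table lacks required column {col!r}")
    pol = table["polarity"].to_numpy()
    bad = set(np.unique(pol)) - set(POLARITY_LEVELS)
    if bad:
        raise ConfigError(f"unknown polarity labels {bad}")
    n = len(table)
    pol_idx = (pol == "Off").astype(int)

    X_pol = np.zeros((n, 2))
    X_pol[np.arange(n), pol_idx] = 1.0

    bin_idx, edges, _ = depth_bin_index(
        table["depth"].to_numpy(dtype=float), n_bins=n_bins, depth_range=depth_range
    )
    X_depth = np.zeros((n, 2 * n_bins))
    X_depth[np.arange(n), pol_idx * n_bins + bin_idx] = 1.0
    empty_cols = tuple(int(j) for j in np.flatnonzero(X_depth.sum(axis=0) == 0))

    batch_ids = tuple(sorted(pd.unique(table["batch"])))
    rank = {b: i for i, b in enumerate(batch_ids)}
    batch_rank = np.array([rank[b] for b in table["batch"]], dtype=int)
    n_enc = len(batch_ids) - 1
    X_batch = np.zeros((n, 2 * max(n_enc, 0)))
    nonref = batch_rank > 0
    X_batch[np.flatnonzero(nonref), (batch_rank[nonref] - 1) * 2 + pol_idx[nonref]] = 1.0

    return DesignMatrixSet(
        X_polarity=X_pol,
        X_depth=X_depth,
        X_batch=X_batch,
        bin_edges=edges,
        batch_ids=batch_ids,
        n_bins=n_bins,
        empty_depth_cols=empty_cols,
    )


def orthogonalize_batch(dset: DesignMatrixSet) -> DesignMatrixSet:
    """Remove the depth design's column space from the batch predictors.

    X_batch_orth = X_batch - P X_batch, with P the orthogonal projector onto
    span(X_depth) (via least squares, so rank deficiency is handled by the
    pseudoinverse).  After this, X_depth' X_batch_orth = 0 to numerical
    precision, and any response variance expressible by depth alone can no
    longer be claimed by the batch predictors.
    """
    coefs, *_ = np.linalg.lstsq(dset.X_depth, dset.X_batch, rcond=None)
    dset.X_batch_orth = dset.X_batch - dset.X_depth @ coefs
    return dset


@dataclass
class LinearFit:
    """Least-squares fit of Y on an indicator design, with per-ROI E.V."""

    weights: np.ndarray          # (P, T)
    fitted: np.ndarray           # (N, T)
    ev: np.ndarray               # (N,) per-ROI explained variance (nan where Var[y]=0)
    mean_ev: float
    sem2: float


def explained_variance(y: np.ndarray, yhat: np.ndarray) -> float:
    """E.V. = 1 - E[(y - y_hat)^2] / Var[y] for one trace.

    Can be negative when the prediction is worse than the trace's mean.
    """
    y = np.asarray(y, dtype=float)
    var = np.var(y)
    if var <= 0:
        raise ConfigError("explained variance undefined for a zero-variance trace")
    return float(1.0 - np.mean((y - np.asarray(yhat, dtype=float)) ** 2) / var)


def explained_variance_summary(Y: np.ndarray, Yhat: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Per-ROI E.V. plus (mean, 2 SEM) over ROIs; zero-variance ROIs are excluded."""
    resid = np.mean((Y - Yhat) ** 2, axis=1)
    var = np.var(Y, axis=1)
    ev = np.full(Y.shape[0], np.nan)
    ok = var > 0
    if not np.all(ok):
        warnings.warn(
            f"{int(np.sum(~ok))} zero-variance ROI(s) excluded from explained variance",
            stacklevel=2,
        )
    ev[ok] = 1.0 - resid[ok] / var[ok]
    vals = ev[ok]
    mean = float(np.mean(vals)) if vals.size else float("nan")
    sem2 = float(2.0 * np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    return ev, mean, sem2


def fit_ols(X: np.ndarray, Y: np.ndarray) -> LinearFit:
    """Least-squares weights W minimizing ||Y - X W||^2.

    For pure indicator designs the rows of W are group-mean traces (e.g. the
    polarity-only model simply averages all On and all Off ROIs).  If the design
    has more columns than rows, the minimum-norm solution is returned with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] > X.shape[0]:
        warnings.warn(
            f"design has more predictors ({X.shape[1]}) than ROIs ({X.shape[0]}); "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    W, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ W
    ev, mean, sem2 = explained_variance_summary(Y, fitted)
    return LinearFit(weights=W, fitted=fitted, ev=ev, mean_ev=mean, sem2=sem2)


def compare_models(Y: np.ndarray, dset: DesignMatrixSet) -> pd.DataFrame:
    """Fit the four nested models and tabulate mean E.V. with 2 SEM.

    Models: polarity only; depth (10 bins per polarity); batch (per batch and
    polarity, reference omitted); and the combined depth + orthogonalized-batch
    model.  Rows are ordered as listed.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != dset.X_polarity.shape[0]:
        raise ConfigError("trace matrix and designs have different ROI counts")
    if dset.X_batch_orth is None:
        orthogonalize_batch(dset)
    designs = {
        "polarity": dset.X_polarity,
        "depth": dset.X_depth,
        "batch": dset.X_batch,
        "batch+depth": np.hstack([dset.X_depth, dset.X_batch_orth]),
    }
    rows = []
    fits = {}
    for name, X in designs.items():
        fit = fit_ols(X, Y)
        fits[name] = fit
        rows.append({
            "model": name,
            "mean_ev": fit.mean_ev,
            "sem2": fit.sem2,
            "n_predictors": X.shape[1],
        })
    out = pd.DataFrame(rows)
    out.attrs["fits"] = fits
    return out
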