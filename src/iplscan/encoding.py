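"""Shared-kernel linear-nonlinear encoding model with temporal stretch.

The model predicts each ROI's chirp response as a causal convolution of the
stimulus with a temporal kernel, passed through an exponential linear unit:

    y_hat_i = g(beta_i + a_i * (f_i * x)),   g(v) = v (v >= 0),  e^v - 1 (v < 0)

The kernel f_i spans 64 taps (1 s at 64 Hz) and is parameterized in a truncated
Fourier basis (frequencies k = 0..21 cycles per kernel length; one constant basis
function at k = 0).  A per-ROI stretch factor alpha_i rescales all basis
frequencies — larger alpha means a faster, more compressed kernel — and a soft
sigmoidal mask zeroes the kernel tail beyond one stretched cycle (t > 1/alpha)
so that compressed kernels do not wrap into a second cycle.

Model classes, from most to least flexible:

* ``per_roi_kernel``      — one free kernel per ROI (alpha fixed at 1).
* ``per_roi_stretch``     — one shared kernel; per-ROI stretch, scale and offset.
* ``depth_batch_interaction`` — shared kernel; stretch omega_{b,j} per (batch, depth-bin) cell.
* ``depth_plus_batch``    — shared kernel; stretch xi_j per depth bin plus an
  additive per-batch shift psi_b (the batch-effect model).
* ``depth_stretch``       — shared kernel; stretch xi_j from depth alone.

All parameters are fitted jointly by full-batch Adam on the mean squared error,
with hand-derived analytic gradients; per-ROI stretches additionally get periodic
grid searches to escape phase-aliasing local minima.  Fits are deterministic
given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

from .errors import ConfigError, InvalidParameterError

__all__ = [
    "N_TAPS",
    "K_MAX",
    "N_COEF",
    "VARIANTS",
    "Kernel",
    "FitConfig",
    "StretchCovariates",
    "SharedKernelModel",
    "fourier_basis",
    "soft_mask",
    "build_kernel",
    "elu",
    "lag_matrix",
    "predict_response",
    "stretch_from_covariates",
    "fit_model",
    "fit_variant_chain",
    "compare_variants",
    "kernel_zero_crossing",
    "speed_profile",
    "explained_variance_rows",
]

N_TAPS = 64          # kernel taps: 1 s at 64 Hz
K_MAX = 21           # highest Fourier frequency (cycles per kernel length)
N_COEF = 2 * K_MAX + 1   # one constant + sin/cos pairs for k = 1..K_MAX
MASK_SHARPNESS = 1.0 / 64.0   # sigmoid sharpness: one tap
ALPHA_FLOOR = 1e-2

VARIANTS = (
    "per_roi_kernel",
    "per_roi_stretch",
    "depth_batch_interaction",
    "depth_plus_batch",
    "depth_stretch",
)
_COVARIATE_VARIANTS = ("depth_stretch", "depth_plus_batch", "depth_batch_interaction")


def _tap_times(n_taps: int = N_TAPS) -> np.ndarray:
    """Tap times normalized to [0, 1): t = 0 is 'now', t -> 1 reaches 1 s back."""
    return np.arange(n_taps) / n_taps


def fourier_basis(alpha, n_taps: int = N_TAPS, k_max: int = K_MAX) -> np.ndarray:
    """Stretched Fourier basis, shape ``alpha.shape + (n_taps, 2*k_max+1)``.

    Columns are ordered [constant, sin_1..sin_K, cos_1..cos_K] with angular
    arguments 2*pi*alpha*k*t, so frequency index k means ``alpha * k`` cycles
    per kernel length.
    """
    alpha = np.asarray(alpha, dtype=float)
    t = _tap_times(n_taps)
    k = np.arange(1, k_max + 1)
    ang = 2.0 * np.pi * alpha[..., None, None] * t[:, None] * k[None, :]
    const = np.ones(ang.shape[:-1] + (1,))
    return np.concatenate([const, np.sin(ang), np.cos(ang)], axis=-1)


def soft_mask(alpha, n_taps: int = N_TAPS, sharpness: float = MASK_SHARPNESS) -> np.ndarray:
    """Decreasing sigmoid mask 1/(1+exp((t - 1/alpha)/s)); cuts the tail at t = 1/alpha."""
    alpha = np.asarray(alpha, dtype=float)
    t = _tap_times(n_taps)
    return expit((1.0 / alpha[..., None] - t) / sharpness)


@dataclass(frozen=True)
class Kernel:
    """A realized temporal filter: 64 taps, its stretch and Fourier coefficients."""

    taps: np.ndarray
    alpha: float
    coef: np.ndarray
    rate_hz: float = 64.0

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.taps.size) / self.rate_hz


def build_kernel(w: np.ndarray, alpha: float) -> Kernel:
    """Evaluate the masked Fourier kernel for coefficients ``w`` and stretch ``alpha``.

    ``w`` has 43 entries: [constant, sin_1..21, cos_1..21].
    """
    if not (alpha > 0):
        raise InvalidParameterError(f"stretch alpha must be > 0, got {alpha}")
    w = np.asarray(w, dtype=float)
    if w.shape != (N_COEF,):
        raise InvalidParameterError(f"expected {N_COEF} coefficients, got shape {w.shape}")
    a = np.asarray(float(alpha))
    taps = soft_mask(a) * (fourier_basis(a) @ w)
    return Kernel(taps=taps, alpha=float(alpha), coef=w.copy())


def elu(v: np.ndarray) -> np.ndarray:
    """Exponential linear unit: identity for v >= 0, e^v - 1 below."""
    return np.where(v >= 0, v, np.expm1(np.minimum(v, 0.0)))


def _elu_grad(v: np.ndarray) -> np.ndarray:
    return np.where(v >= 0, 1.0, np.exp(np.minimum(v, 0.0)))


def lag_matrix(x: np.ndarray, n_taps: int = N_TAPS) -> np.ndarray:
    """Causal lag matrix L (T x n_taps) with L[n, tau] = x[n - tau].

    The stimulus is padded at the start with its first value, so the convolution
    (L @ taps) is defined from the first sample on.
    """
    x = np.asarray(x, dtype=float)
    xp = np.concatenate([np.full(n_taps - 1, x[0]), x])
    return sliding_window_view(xp, n_taps)[:, ::-1]


def predict_response(kernel: Kernel, a: float, beta: float, x: np.ndarray,
                     rate_hz: float = 64.0) -> np.ndarray:
    """LN prediction g(beta + a * (f * x)) for a single ROI.

    ``x`` must be sampled at the kernel's rate (64 Hz).
    """
    if abs(rate_hz - kernel.rate_hz) > 1e-9:
        raise InvalidParameterError(
            f"stimulus rate {rate_hz} Hz does not match kernel rate {kernel.rate_hz} Hz"
        )
    x = np.asarray(x, dtype=float)
    xp = np.concatenate([np.full(kernel.taps.size - 1, x[0]), x])
    conv = np.convolve(xp, kernel.taps, mode="valid")
    return elu(beta + a * conv)


# --------------------------------------------------------------------------
# Stretch covariates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StretchCovariates:
    """Per-ROI covariates driving the stretch parameterizations.

    ``cell`` indexes (polarity x depth-bin) cells 0..n_cells-1 (same cells as the
    depth design of the linear models); ``batch`` indexes batches 0..n_batch-1.
    """

    polarity: np.ndarray          # 'On' / 'Off' strings
    cell: np.ndarray              # int cell index per ROI
    batch: np.ndarray             # int batch index per ROI
    n_cells: int
    n_batch: int
    bin_edges: np.ndarray         # depth bin edges (n_bins + 1,)
    n_bins: int
    batch_ids: tuple = ()

    @classmethod
    def from_table(cls, table: pd.DataFrame, n_bins: int = 10,
                   depth_range: tuple[float, float] = (-1.0, 2.0)) -> "StretchCovariates":
        """Build covariates from a table with 'polarity', 'depth', 'batch' columns."""
        from .linmod import depth_bin_index  # local import: avoid cycle at module load

        pol = table["polarity"].to_numpy()
        pol_idx = (pol == "Off").astype(int)   # On = 0, Off = 1
        bin_idx, edges, _ = depth_bin_index(
            table["depth"].to_numpy(dtype=float), n_bins=n_bins, depth_range=depth_range
        )
        cell = pol_idx * n_bins + bin_idx
        batch_ids = tuple(sorted(pd.unique(table["batch"])))
        lookup = {b: i for i, b in enumerate(batch_ids)}
        batch = np.array([lookup[b] for b in table["batch"]], dtype=int)
        return cls(
            polarity=pol, cell=cell, batch=batch,
            n_cells=2 * n_bins, n_batch=len(batch_ids),
            bin_edges=edges, n_bins=n_bins, batch_ids=batch_ids,
        )


def stretch_from_covariates(variant: str, params: dict, cell, batch) -> np.ndarray:
    """Per-ROI stretch alpha from the variant's parameters.

    depth_stretch: xi_j; depth_plus_batch: xi_j + psi_b; interaction: omega_{b,j};
    per_roi_stretch: the ROI's own alpha.  Values at or below zero after summation
    are clipped to a floor (1e-2) with a warning.
    """
    cell = np.asarray(cell, dtype=int)
    batch = np.asarray(batch, dtype=int)
    if variant == "depth_stretch":
        alpha = params["xi"][cell]
    elif variant == "depth_plus_batch":
        alpha = params["xi"][cell] + params["psi"][batch]
    elif variant == "depth_batch_interaction":
        alpha = params["omega"][batch, cell]
    elif variant == "per_roi_stretch":
        alpha = np.asarray(params["alpha"], dtype=float)
    else:
        raise ConfigError(f"variant {variant!r} has no stretch parameterization")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha < ALPHA_FLOOR):
        warnings.warn("stretch fell below floor; clipping to keep alpha > 0", stacklevel=2)
        alpha = np.maximum(alpha, ALPHA_FLOOR)
    return alpha


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_model`.

    ``lr`` is the Adam step size; ``n_iter`` the iteration cap; ``patience`` the
    window (iterations) without improvement after which optimization stops with
    the best iterate.  ``grid_every``/``grid`` control the periodic per-ROI
    stretch grid search (per-ROI variant only); ``ev_tolerance`` is the slack
    allowed when comparing attained explained variance across nested variants.
    """

    lr: float = 0.05
    n_iter: int = 2500
    patience: int = 400
    grid_every: int = 250
    grid_lo: float = 0.4
    grid_hi: float = 2.5
    grid_n: int = 43
    polish_iter: int = 600
    init_w_scale: float = 0.01
    ev_tolerance: float = 0.02


@dataclass
class SharedKernelModel:
    """A fitted encoding model (any variant) with its parameters and diagnostics."""

    variant: str
    w: np.ndarray                      # (43,) shared, or (N, 43) for per_roi_kernel
    a: np.ndarray                      # (N,) scale (fixed at +-1-style init for per_roi_kernel)
    beta: np.ndarray                   # (N,) offsets
    alpha: np.ndarray                  # (N,) realized stretches
    xi: np.ndarray | None = None       # (n_cells,) depth-cell stretch weights
    psi: np.ndarray | None = None      # (n_batch,) additive batch shifts
    omega: np.ndarray | None = None    # (n_batch, n_cells) interaction weights
    covariates: StretchCovariates | None = None
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    ev: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_ev: float = np.nan
    seed: int | None = None
    n_iter_run: int = 0
    converged: bool = True

    def kernel_for_roi(self, i: int) -> Kernel:
        w = self.w[i] if self.w.ndim == 2 else self.w
        return build_kernel(w, float(self.alpha[i]))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted traces (N, T) for a stimulus trace ``x`` at 64 Hz.

        The stimulus is z-scored before convolution (as during fitting); the
        transform is idempotent, so an already-standardized trace is fine.
        """
        x = np.asarray(x, dtype=float)
        sd = np.std(x)
        x = (x - np.mean(x)) / (sd if sd > 0 else 1.0)
        L = lag_matrix(x)
        F = _kernels_matrix(self.w, self.alpha)
        return elu(self.beta[:, None] + self.a[:, None] * (F @ L.T))


def _kernels_matrix(w: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Stack of masked kernels, shape (N, 64)."""
    alpha = np.asarray(alpha, dtype=float)
    mask = soft_mask(alpha)
    B = fourier_basis(alpha)
    if w.ndim == 2:
        core = np.einsum("ntc,nc->nt", B, w)
    else:
        core = B @ w
    return mask * core


def explained_variance_rows(Y: np.ndarray, Yhat: np.ndarray) -> np.ndarray:
    """Per-row explained variance 1 - mean((y-yhat)^2)/var(y)."""
    resid = np.mean((Y - Yhat) ** 2, axis=-1)
    var = np.var(Y, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.0 - resid / var


def _softplus(r):
    return np.logaddexp(0.0, r)


def _softplus_inv(a):
    a = np.asarray(a, dtype=float)
    return a + np.log(-np.expm1(-a))


class _Adam:
    """Minimal Adam over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _realized_alpha(variant: str, params: dict, cov: StretchCovariates | None,
                    n_roi: int) -> tuple[np.ndarray, np.ndarray]:
    """Realized per-ROI alpha and a clip mask (True where alpha was floored)."""
    if variant == "per_roi_kernel":
        return np.ones(n_roi), np.zeros(n_roi, dtype=bool)
    if variant == "per_roi_stretch":
        alpha = _softplus(params["raw_alpha"])
        return alpha, np.zeros(n_roi, dtype=bool)
    assert cov is not None
    if variant == "depth_stretch":
        raw = params["xi"][cov.cell]
    elif variant == "depth_plus_batch":
        raw = params["xi"][cov.cell] + params["psi"][cov.batch]
    else:  # depth_batch_interaction
        raw = params["omega"][cov.batch, cov.cell]
    clipped = raw < ALPHA_FLOOR
    return np.maximum(raw, ALPHA_FLOOR), clipped


def _forward_backward(variant, params, Y, L, cov):
    """Loss and analytic gradients for one iteration. Shapes: Y (N,T), L (T,64)."""
    n_roi, T = Y.shape
    t = _tap_times()
    k = np.arange(1, K_MAX + 1)

    alpha, clipped = _realized_alpha(variant, params, cov, n_roi)
    a, beta = params["a"], params["beta"]

    ang = 2.0 * np.pi * alpha[:, None, None] * t[None, :, None] * k[None, None, :]
    sin_a, cos_a = np.sin(ang), np.cos(ang)
    mask = soft_mask(alpha)                       # (N, 64)

    w = params["w"]
    if variant == "per_roi_kernel":
        ws, wc = w[:, 1:K_MAX + 1], w[:, K_MAX + 1:]
        core = w[:, :1] + np.einsum("ntk,nk->nt", sin_a, ws) + np.einsum("ntk,nk->nt", cos_a, wc)
    else:
        ws, wc = w[1:K_MAX + 1], w[K_MAX + 1:]
        core = w[0] + sin_a @ ws + cos_a @ wc     # (N, 64)
    F = mask * core
    C = F @ L.T                                   # (N, T)
    z = beta[:, None] + a[:, None] * C
    yhat = elu(z)
    resid = yhat - Y
    loss = float(np.mean(resid**2))

    G = (2.0 / (n_roi * T)) * resid * _elu_grad(z)
    grads: dict[str, np.ndarray] = {
        "beta": G.sum(axis=1),
        "a": np.einsum("nt,nt->n", G, C),
    }
    dF = (a[:, None] * G) @ L                     # (N, 64)

    if variant == "per_roi_kernel":
        dcore = dF * mask
        gw = np.empty_like(w)
        gw[:, 0] = dcore.sum(axis=1)
        gw[:, 1:K_MAX + 1] = np.einsum("nt,ntk->nk", dcore, sin_a)
        gw[:, K_MAX + 1:] = np.einsum("nt,ntk->nk", dcore, cos_a)
        grads["w"] = gw
        return loss, grads, alpha

    dcore = dF * mask
    gw = np.empty(N_COEF)
    gw[0] = dcore.sum()
    gw[1:K_MAX + 1] = np.einsum("nt,ntk->k", dcore, sin_a)
    gw[K_MAX + 1:] = np.einsum("nt,ntk->k", dcore, cos_a)
    grads["w"] = gw

    # d core / d alpha = sum_k 2 pi k t (ws cos - wc sin)
    dcore_dalpha = 2.0 * np.pi * t[None, :] * (
        np.einsum("ntk,k->nt", cos_a, k * ws) - np.einsum("ntk,k->nt", sin_a, k * wc)
    )
    dmask_dalpha = -(mask * (1 - mask)) / (MASK_SHARPNESS * alpha[:, None] ** 2)
    galpha = np.einsum("nt,nt->n", dF, dmask_dalpha * core + mask * dcore_dalpha)
    galpha = np.where(clipped, 0.0, galpha)

    if variant == "per_roi_stretch":
        grads["raw_alpha"] = galpha * expit(params["raw_alpha"])
    elif variant == "depth_stretch":
        gxi = np.zeros_like(params["xi"])
        np.add.at(gxi, cov.cell, galpha)
        grads["xi"] = gxi
    elif variant == "depth_plus_batch":
        gxi = np.zeros_like(params["xi"])
        np.add.at(gxi, cov.cell, galpha)
        gpsi = np.zeros_like(params["psi"])
        np.add.at(gpsi, cov.batch, galpha)
        grads["xi"], grads["psi"] = gxi, gpsi
    else:  # depth_batch_interaction
        gom = np.zeros_like(params["omega"])
        np.add.at(gom, (cov.batch, cov.cell), galpha)
        grads["omega"] = gom
    return loss, grads, alpha


def _per_roi_sse(params_w, a, beta, alpha_cands, Y, L):
    """SSE per (candidate, ROI) for shared-kernel stretch candidates.

    ``alpha_cands`` is (n_cand,) shared or (n_cand, N) per-ROI.
    """
    n_cand = alpha_cands.shape[0]
    out = np.empty((n_cand, Y.shape[0]))
    for c in range(n_cand):
        ac = alpha_cands[c] if alpha_cands.ndim == 2 else np.full(Y.shape[0], alpha_cands[c])
        F = _kernels_matrix(params_w, ac)
        z = beta[:, None] + a[:, None] * (F @ L.T)
        out[c] = np.sum((elu(z) - Y) ** 2, axis=1)
    return out


def _grid_refine_alpha(params, Y, L, cfg: FitConfig) -> None:
    """Per-ROI stretch grid search at the current shared kernel (in place)."""
    grid = np.geomspace(cfg.grid_lo, cfg.grid_hi, cfg.grid_n)
    cur = _softplus(params["raw_alpha"])
    cands = np.concatenate([grid[:, None] * np.ones((1, cur.size)), cur[None, :]])
    sse = _per_roi_sse(params["w"], params["a"], params["beta"], cands, Y, L)
    best = np.argmin(sse, axis=0)
    new_alpha = np.where(best < grid.size, grid[np.minimum(best, grid.size - 1)], cur)
    params["raw_alpha"] = _softplus_inv(np.maximum(new_alpha, ALPHA_FLOOR))


def _gauge_refine(params, Y, L, cov, lr: float, n_s: int = 9,
                  span: tuple[float, float] = (0.7, 1.43), refit_iter: int = 150) -> None:
    """Search along the stretch-gauge direction (in place).

    The shared-kernel stretch model is nearly degenerate under rescaling all
    per-ROI stretches by a common factor s while compressing the kernel by 1/s
    (exactly degenerate only at s = 1, because basis frequencies are integers).
    Gradient descent settles at an arbitrary point in this shallow valley, so
    each candidate gauge is evaluated properly: jump (rescale the stretches,
    re-project the kernel onto the integer-frequency basis), briefly re-fit the
    kernel/scales/offsets with the stretches frozen, and keep the gauge with
    the lowest re-fitted loss.
    """
    alpha = _softplus(params["raw_alpha"])
    one = np.asarray(1.0)
    # current parameters (no jump, no refit) seed the comparison, so the
    # search can only improve the loss
    best_loss, _, _ = _forward_backward("per_roi_stretch", params, Y, L, cov)
    best_params = {k: v.copy() for k, v in params.items()}
    for s in np.geomspace(span[0], span[1], n_s):
        cand = {k: v.copy() for k, v in params.items()}
        if s != 1.0:
            core = soft_mask(one) * (fourier_basis(np.asarray(1.0 / s)) @ params["w"])
            cand["w"] = project_taps_onto_basis(core)
            cand["raw_alpha"] = _softplus_inv(np.maximum(s * alpha, ALPHA_FLOOR))
        opt = _Adam(cand, lr)
        loss = np.inf
        for _ in range(refit_iter):
            loss, grads, _ = _forward_backward("per_roi_stretch", cand, Y, L, cov)
            grads.pop("raw_alpha", None)   # stretches frozen during re-fit
            opt.step(cand, grads)
        if loss < best_loss:
            best_loss, best_params = loss, cand
    if best_params is not None:
        params.update(best_params)


def _parabolic_refine_alpha(params, Y, L, n_ratio: int = 15, span: float = 0.12) -> None:
    """Local log-scale refinement of per-ROI stretches around their current values."""
    cur = _softplus(params["raw_alpha"])
    ratios = np.geomspace(1.0 - span, 1.0 + span, n_ratio)
    cands = ratios[:, None] * cur[None, :]
    sse = _per_roi_sse(params["w"], params["a"], params["beta"], cands, Y, L)
    best = np.argmin(sse, axis=0)
    log_r = np.log(ratios)
    refined = cur * ratios[best]
    interior = (best > 0) & (best < n_ratio - 1)
    if np.any(interior):
        i = best[interior]
        cols = np.where(interior)[0]
        y0, y1, y2 = sse[i - 1, cols], sse[i, cols], sse[i + 1, cols]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-30, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = log_r[1] - log_r[0]
        refined[cols] = cur[cols] * np.exp(log_r[i] + shift * step)
    # accept refinements only where they do not worsen the fit
    sse_ref = _per_roi_sse(params["w"], params["a"], params["beta"], refined[None, :], Y, L)[0]
    sse_cur = _per_roi_sse(params["w"], params["a"], params["beta"], cur[None, :], Y, L)[0]
    keep = sse_ref <= sse_cur
    params["raw_alpha"] = _softplus_inv(np.maximum(np.where(keep, refined, cur), ALPHA_FLOOR))


def _init_params(variant, Y, cov, cfg, rng, init):
    n_roi = Y.shape[0]
    if cov is not None:
        pol_sign = np.where(cov.polarity == "Off", -1.0, 1.0)
    else:
        pol_sign = np.ones(n_roi)
    params: dict[str, np.ndarray] = {
        "a": pol_sign.astype(float),
        "beta": np.zeros(n_roi),
    }
    if variant == "per_roi_kernel":
        params["w"] = cfg.init_w_scale * rng.standard_normal((n_roi, N_COEF))
        params["a"] = pol_sign.astype(float)
    else:
        params["w"] = cfg.init_w_scale * rng.standard_normal(N_COEF)
    if variant == "per_roi_stretch":
        params["raw_alpha"] = np.full(n_roi, float(_softplus_inv(1.0)))
    elif variant == "depth_stretch":
        params["xi"] = np.ones(cov.n_cells)
    elif variant == "depth_plus_batch":
        params["xi"] = np.ones(cov.n_cells)
        params["psi"] = np.zeros(cov.n_batch)
    elif variant == "depth_batch_interaction":
        params["omega"] = np.ones((cov.n_batch, cov.n_cells))
    if init:
        for key, val in init.items():
            if key in params:
                params[key] = np.array(val, dtype=float, copy=True)
    return params


def project_taps_onto_basis(taps: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Least-squares Fourier coefficients reproducing ``taps`` at stretch ``alpha``."""
    a = np.asarray(float(alpha))
    design = soft_mask(a)[:, None] * fourier_basis(a)
    coef, *_ = np.linalg.lstsq(design, np.asarray(taps, dtype=float), rcond=None)
    return coef


def fit_model(
    variant: str,
    traces: np.ndarray,
    stimulus: np.ndarray,
    covariates: StretchCovariates | pd.DataFrame | None = None,
    config: FitConfig | None = None,
    seed: int = 0,
    init: dict | None = None,
) -> SharedKernelModel:
    """Fit one encoding-model variant to repeat-averaged traces.

    Parameters
    ----------
    traces : (N, T) array
        Repeat-averaged, detrended responses at 64 Hz.
    stimulus : (T,) array
        Chirp intensity trace at 64 Hz; z-scored internally before convolution.
    covariates : StretchCovariates or DataFrame
        Required for the depth/batch variants; for per-ROI variants only the
        polarity column is used (sign initialization of the scale a_i).
    init : dict, optional
        Warm-start values for any parameter array (used for nested-variant chains).
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    cfg = config or FitConfig()
    Y = np.asarray(traces, dtype=float)
    x = np.asarray(stimulus, dtype=float)
    if Y.ndim != 2:
        raise ConfigError("traces must be a 2-D (N, T) array")
    if x.shape[0] != Y.shape[1]:
        raise ConfigError("stimulus length must match trace length")
    if isinstance(covariates, pd.DataFrame):
        covariates = StretchCovariates.from_table(covariates)
    if variant in _COVARIATE_VARIANTS and covariates is None:
        raise ConfigError(f"variant {variant!r} requires depth/batch covariates")

    sd = np.std(x)
    xz = (x - np.mean(x)) / (sd if sd > 0 else 1.0)
    L = lag_matrix(xz)

    rng = np.random.default_rng(seed)
    params = _init_params(variant, Y, covariates, cfg, rng, init)
    opt = _Adam(params, cfg.lr)

    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    losses = []
    since_best = 0
    n_run = 0
    for it in range(cfg.n_iter):
        n_run = it + 1
        if (
            variant == "per_roi_stretch"
            and cfg.grid_every > 0
            and it > 0
            and it % cfg.grid_every == 0
        ):
            _grid_refine_alpha(params, Y, L, cfg)
            opt.m.pop("raw_alpha", None)
            opt.m["raw_alpha"] = np.zeros_like(params["raw_alpha"])
            opt.v["raw_alpha"] = np.zeros_like(params["raw_alpha"])
        loss, grads, _ = _forward_backward(variant, params, Y, L, covariates)
        losses.append(loss)
        if loss < best_loss - 1e-14:
            best_loss = loss
            best_params = {k: v.copy() for k, v in params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
        opt.step(params, grads)

    converged = since_best <= cfg.patience
    params = best_params

    if variant == "per_roi_stretch" and cfg.polish_iter > 0:
        # final polish: gauge search, per-ROI stretch line search, short Adam
        _gauge_refine(params, Y, L, covariates, cfg.lr)
        # restart best-iterate tracking in the chosen gauge (the search itself
        # never returns a worse loss than the pre-polish best)
        best_loss, _, _ = _forward_backward(variant, params, Y, L, covariates)
        best_params = {k: v.copy() for k, v in params.items()}
        for _ in range(2):
            _parabolic_refine_alpha(params, Y, L)
            opt2 = _Adam(params, cfg.lr * 0.2)
            for _ in range(cfg.polish_iter // 2):
                loss, grads, _ = _forward_backward(variant, params, Y, L, covariates)
                losses.append(loss)
                if loss < best_loss:
                    best_loss = loss
                    best_params = {k: v.copy() for k, v in params.items()}
                opt2.step(params, grads)
        params = best_params

    if not converged:
        warnings.warn(
            "encoding-model fit stopped before the loss plateaued; returning best iterate",
            stacklevel=2,
        )

    alpha, _ = _realized_alpha(variant, params, covariates, Y.shape[0])
    model = SharedKernelModel(
        variant=variant,
        w=params["w"],
        a=params["a"],
        beta=params["beta"],
        alpha=alpha,
        xi=params.get("xi"),
        psi=params.get("psi"),
        omega=params.get("omega"),
        covariates=covariates,
        loss_trace=np.asarray(losses),
        seed=seed,
        n_iter_run=n_run,
        converged=converged,
    )
    yhat = model.predict(xz)
    model.ev = explained_variance_rows(Y, yhat)
    model.mean_ev = float(np.mean(model.ev))
    return model


_CHAIN_ORDER = (
    "depth_stretch",
    "depth_plus_batch",
    "depth_batch_interaction",
    "per_roi_stretch",
    "per_roi_kernel",
)


def fit_variant_chain(
    traces: np.ndarray,
    stimulus: np.ndarray,
    covariates: StretchCovariates | pd.DataFrame,
    variants: tuple[str, ...] = _CHAIN_ORDER,
    config: FitConfig | None = None,
    seed: int = 0,
) -> dict[str, SharedKernelModel]:
    """Fit nested variants from most to least constrained, warm-starting each
    richer model from the previous fit.

    The warm start makes the attained explained variance respect model-class
    nesting (each richer class starts at, and can only improve on, the best
    constrained solution).
    """
    if isinstance(covariates, pd.DataFrame):
        covariates = StretchCovariates.from_table(covariates)
    cfg = config or FitConfig()
    fits: dict[str, SharedKernelModel] = {}
    prev: SharedKernelModel | None = None
    for variant in _CHAIN_ORDER:
        if variant not in variants:
            continue
        init: dict | None = None
        if prev is not None:
            init = {"a": prev.a, "beta": prev.beta}
            if variant == "per_roi_kernel":
                # project each ROI's realized kernel onto the unstretched basis,
                # folding the scale a_i into the per-ROI coefficients
                w_i = np.stack([
                    project_taps_onto_basis(prev.a[i] * prev.kernel_for_roi(i).taps)
                    for i in range(traces.shape[0])
                ])
                init = {"w": w_i, "a": np.ones(traces.shape[0]), "beta": prev.beta}
            else:
                init["w"] = prev.w
                if variant == "per_roi_stretch":
                    init["raw_alpha"] = _softplus_inv(np.maximum(prev.alpha, ALPHA_FLOOR))
                elif variant == "depth_plus_batch" and prev.variant == "depth_stretch":
                    init["xi"] = prev.xi
                    init["psi"] = np.zeros(covariates.n_batch)
                elif variant == "depth_batch_interaction":
                    if prev.psi is not None:
                        init["omega"] = prev.xi[None, :] + prev.psi[:, None]
                    elif prev.xi is not None:
                        init["omega"] = np.tile(prev.xi, (covariates.n_batch, 1))
        fits[variant] = fit_model(
            variant, traces, stimulus, covariates, config=cfg, seed=seed, init=init
        )
        prev = fits[variant]
    return fits


def compare_variants(fits: dict[str, SharedKernelModel]) -> pd.DataFrame:
    """Tabulate mean explained variance (and 2 SEM across ROIs) per variant."""
    rows = []
    for variant, m in fits.items():
        ev = m.ev[np.isfinite(m.ev)]
        rows.append({
            "variant": variant,
            "mean_ev": float(np.mean(ev)),
            "sem2": float(2.0 * np.std(ev, ddof=1) / np.sqrt(ev.size)) if ev.size > 1 else np.nan,
            "n_roi": int(m.ev.size),
        })
    return pd.DataFrame(rows)


def kernel_zero_crossing(kernel: Kernel) -> float:
    """Time (s) of the first sign change after the kernel's first peak.

    The first peak is the absolute-maximum tap; the crossing time is linearly
    interpolated between the straddling taps.  Returns ``nan`` when the kernel
    never changes sign after the peak (undefined marker).
    """
    taps = kernel.taps
    if taps.size == 0 or not np.any(np.abs(taps) > 0):
        return float("nan")
    p = int(np.argmax(np.abs(taps)))
    s0 = np.sign(taps[p])
    for j in range(p + 1, taps.size):
        if np.sign(taps[j]) != s0 and taps[j] != taps[j - 1]:
            frac = taps[j - 1] / (taps[j - 1] - taps[j])
            return float((j - 1 + frac) / kernel.rate_hz)
    return float("nan")


def speed_profile(model: SharedKernelModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stretch per depth bin per polarity, plus the distribution of batch shifts.

    Only defined for the depth-binned variants.  Returns ``(profile, psi_table)``;
    ``psi_table`` is empty for the depth-only variant.  Cells with no ROIs are
    flagged (``n_roi = 0``) — their stretch is the untrained initial value for
    xi/omega-based variants.
    """
    if model.variant not in _COVARIATE_VARIANTS:
        raise ConfigError(f"variant {model.variant!r} has no depth-bin speed profile")
    cov = model.covariates
    assert cov is not None
    n_bins = cov.n_bins
    counts = np.bincount(cov.cell, minlength=cov.n_cells)
    if model.variant == "depth_batch_interaction":
        batch_counts = np.zeros((cov.n_batch, cov.n_cells), dtype=float)
        np.add.at(batch_counts, (cov.batch, cov.cell), 1.0)
        with np.errstate(invalid="ignore"):
            cell_speed = np.where(
                counts > 0, np.sum(model.omega * batch_counts, axis=0) / np.maximum(counts, 1), np.nan
            )
    else:
        cell_speed = model.xi.copy()
    mids = 0.5 * (cov.bin_edges[:-1] + cov.bin_edges[1:])
    rows = []
    for pol_idx, pol in enumerate(("On", "Off")):
        for j in range(n_bins):
            cell = pol_idx * n_bins + j
            rows.append({
                "polarity": pol,
                "bin": j,
                "depth_mid": float(mids[j]),
                "stretch": float(cell_speed[cell]),
                "n_roi": int(counts[cell]),
            })
    profile = pd.DataFrame(rows)
    if model.psi is not None:
        psi_table = pd.DataFrame({
            "batch": list(cov.batch_ids) if cov.batch_ids else list(range(model.psi.size)),
            "psi": model.psi,
        })
    else:
        psi_table = pd.DataFrame(columns=["batch", "psi"])
    return profile, psi_table
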