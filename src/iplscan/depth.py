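"""ChAT-band-normalized IPL depth registration and polarity-switch alignment.

IPL depth is expressed in ChAT units: the On cholinergic (starburst) band is 0,
the Off band is 1, the ganglion-cell-layer border sits near -1 and the
inner-nuclear-layer border near +2.  When the ChAT bands are not labelled, the
band positions are inferred from the IPL borders using the measured border
positions in ChAT units (GCL -1.1, INL 1.9 by default).

Because absolute landmark placement varies between scan fields, fields are
additionally aligned functionally: the IPL depth at which response polarity
switches from On to Off is located via the first principal component of the
chirp responses and a logistic fit, subtracted per field, and the IPL centre is
re-anchored at 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import InvalidParameterError
from .stimulus import ChirpStimulus

__all__ = [
    "DepthAssignment",
    "DEFAULT_BORDER_DEPTHS",
    "DEFAULT_SWITCH",
    "depth_from_landmarks",
    "bands_from_borders",
    "polarity_and_switch",
    "align_depths",
    "logistic_midpoint",
]

DEFAULT_BORDER_DEPTHS = (-1.1, 1.9)   # (GCL, INL) in ChAT units
DEFAULT_SWITCH = 0.24                  # fallback polarity-switch depth (population mean)


@dataclass
class DepthAssignment:
    """Depth bookkeeping for one ROI."""

    roi_id: int
    raw_depth: float
    aligned_depth: float
    polarity: str
    switch_depth: float


def depth_from_landmarks(position_um: float, on_band_um: float, off_band_um: float) -> float:
    """Affine map sending the On ChAT band to 0 and the Off band to 1."""
    if on_band_um == off_band_um:
        raise InvalidParameterError("ChAT band positions must be distinct")
    return (position_um - on_band_um) / (off_band_um - on_band_um)


def bands_from_borders(
    gcl_border_um: float,
    inl_border_um: float,
    border_depths: tuple[float, float] = DEFAULT_BORDER_DEPTHS,
) -> tuple[float, float]:
    """Infer ChAT band positions (µm) from the IPL borders.

    Solves the affine depth map that places the GCL border at ``border_depths[0]``
    (default -1.1) and the INL border at ``border_depths[1]`` (default 1.9), and
    returns the positions mapping to depths 0 (On band) and 1 (Off band).
    """
    if gcl_border_um == inl_border_um:
        raise InvalidParameterError("IPL border positions must be distinct")
    d_gcl, d_inl = border_depths
    if d_gcl == d_inl:
        raise InvalidParameterError("border depth values must be distinct")
    scale = (inl_border_um - gcl_border_um) / (d_inl - d_gcl)
    on_band = gcl_border_um + (0.0 - d_gcl) * scale
    off_band = gcl_border_um + (1.0 - d_gcl) * scale
    return on_band, off_band


def logistic_midpoint(depths: np.ndarray, is_off: np.ndarray) -> float:
    """50 %-point of a 1-D logistic fit of the Off label on depth.

    A mild ridge penalty keeps the fit defined and deterministic even for
    perfectly separable fields (the midpoint then falls between the groups).
    """
    clf = LogisticRegression(C=1e3, solver="lbfgs", max_iter=1000)
    clf.fit(np.asarray(depths, dtype=float).reshape(-1, 1), np.asarray(is_off, dtype=int))
    coef = float(clf.coef_[0, 0])
    if coef == 0:
        return float(np.median(depths))
    return float(-clf.intercept_[0] / coef)


def polarity_and_switch(
    traces: np.ndarray,
    raw_depths: np.ndarray,
    stimulus: ChirpStimulus,
    fallback_switch: float = DEFAULT_SWITCH,
) -> tuple[np.ndarray, float]:
    """Polarity labels and the polarity-switch depth for one scan field.

    The first principal component of the row-centred trace matrix separates On
    from Off responses; its sign is anchored so that the component rises during
    the stimulus On step (PCA sign is otherwise arbitrary).  Polarity is the
    sign of each ROI's projection, and the switch depth is the 50 %-point of a
    logistic fit of polarity against raw depth.  Fields containing a single
    polarity fall back to the configured default switch (0.24) with a warning.
    """
    Y = np.asarray(traces, dtype=float)
    depths = np.asarray(raw_depths, dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    _, _, Vt = np.linalg.svd(Yc, full_matrices=False)
    pc1 = Vt[0]

    step = stimulus.segment_slice("step")
    base = stimulus.segment_slice("baseline")
    if np.mean(pc1[step]) - np.mean(pc1[base]) < 0:
        pc1 = -pc1
    proj = Yc @ pc1
    polarity = np.where(proj > 0, "On", "Off")

    if len(set(polarity)) < 2:
        warnings.warn(
            f"field has a single polarity; using fallback switch depth {fallback_switch}",
            stacklevel=2,
        )
        return polarity, float(fallback_switch)
    switch = logistic_midpoint(depths, polarity == "Off")
    return polarity, switch


def align_depths(raw_depths: np.ndarray, switch_depth: float) -> np.ndarray:
    """Re-anchor depths so the field's polarity switch sits at the IPL centre:
    aligned = raw - switch + 0.5.  Affine, hence order-preserving."""
    if not np.isfinite(switch_depth):
        raise InvalidParameterError("switch depth must be finite")
    return np.asarray(raw_depths, dtype=float) - switch_depth + 0.5
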