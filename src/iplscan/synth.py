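"""Synthetic ground-truth data: ROI populations, repeat traces and x-z movies.

The generator emulates the statistical structure of chirp-evoked glutamate
signals in axial IPL scans:

* ROI depths span the ChAT-normalized IPL axis from -1 (ganglion-cell-layer
  border) to +2 (inner-nuclear-layer border); polarity is On below the IPL
  centre and Off above it.
* Response speed (the temporal stretch alpha) follows a unimodal depth profile
  peaked at the IPL centre, with a plateau on the On side beyond the On ChAT
  band and a continued decline on the Off side.
* Each scan field (batch) carries an additive zero-mean speed shift psi_b,
  the dominant batch effect.
* Traces are generated by the same shared-kernel LN model used for fitting
  (one shared prediction code path), with i.i.d. Gaussian noise per repeat.
* Movies plant connected ROI blobs into a 64 x 56 pixel field (1.6 ms/line)
  with per-pixel noise, a depth-dependent labelling gradient and high-variance
  ETL-settling artefact lines at the start of each frame.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import build_kernel, predict_response, project_taps_onto_basis
from .errors import ConfigError, PlacementError
from .stimulus import ChirpStimulus, generate_chirp

__all__ = [
    "PopulationConfig",
    "GroundTruthROI",
    "SimTruth",
    "SimTraces",
    "MovieConfig",
    "Movie",
    "default_kernel_coef",
    "default_speed_profile",
    "sample_population",
    "simulate_traces",
    "render_movie",
    "population_table",
    "write_movie_tiff",
]


def default_kernel_coef() -> np.ndarray:
    """Fourier coefficients of the default biphasic ground-truth kernel.

    The target waveform is a difference of two gamma-like lobes (fast positive,
    slower negative), a standard shape for bipolar-cell temporal receptive
    fields; it is projected once onto the masked Fourier basis at stretch 1.
    """
    t = np.arange(64) / 64.0
    lobe = lambda tau: (t / tau) * np.exp(1.0 - t / tau)  # noqa: E731 — peaks at tau, max 1
    fast, slow = lobe(0.05), lobe(0.12)
    # integral-normalized difference: transient, biphasic, small net-positive DC
    # (so a light increment drives an On terminal up both at onset and sustained)
    target = fast / fast.sum() - 0.8 * slow / slow.sum()
    target /= np.max(np.abs(target))
    return project_taps_onto_basis(target, alpha=1.0)


def default_speed_profile(bin_mids: np.ndarray) -> np.ndarray:
    """Unimodal depth->speed profile: Gaussian peak at the IPL centre (0.5),
    falling off towards both borders, with a plateau on the On side beyond the
    On ChAT band (depth < 0)."""
    mids = np.asarray(bin_mids, dtype=float)
    base, amp, width = 0.7, 0.7, 0.6
    prof = base + amp * np.exp(-(((mids - 0.5) / width) ** 2))
    plateau = base + amp * np.exp(-((0.5 / width) ** 2))
    return np.where(mids < 0.0, plateau, prof)


@dataclass(frozen=True)
class PopulationConfig:
    """Ground-truth population settings.

    ``psi_sd`` is the s.d. of the zero-mean per-batch speed shifts; ``centre``
    the aligned depth of the On/Off polarity switch; noise is additive i.i.d.
    Gaussian per 64 Hz sample.
    """

    depth_range: tuple[float, float] = (-1.0, 2.0)
    n_bins: int = 10
    centre: float = 0.5
    psi_sd: float = 0.15
    amplitude_sigma: float = 0.25     # lognormal sigma of |a_i|
    offset_sd: float = 0.05
    noise_sigma: float = 0.5
    repeats: int = 4


@dataclass(frozen=True)
class GroundTruthROI:
    """One simulated ROI: identity, covariates and generative parameters."""

    roi_id: int
    batch_id: str
    depth: float
    polarity: str        # 'On' | 'Off'
    amplitude: float     # signed scale a_i (On positive, Off negative)
    offset: float        # beta_i
    stretch: float       # alpha_i
    noise_sigma: float


@dataclass
class SimTruth:
    """Ground truth of a synthetic dataset, for parameter-recovery tests."""

    kernel_coef: np.ndarray            # (43,) shared Fourier coefficients
    xi: np.ndarray                     # (n_bins,) depth-bin speed weights
    psi: np.ndarray                    # (n_batch,) batch shifts
    bin_edges: np.ndarray              # (n_bins + 1,)
    centre: float
    seed: int
    batch_ids: tuple = ()
    config: PopulationConfig = field(default_factory=PopulationConfig)


def sample_population(
    n_roi: int,
    n_batch: int,
    config: PopulationConfig | None = None,
    seed: int = 0,
) -> tuple[list[GroundTruthROI], SimTruth]:
    """Draw a ground-truth ROI population.

    Depths are uniform over the depth range; polarity is On below ``centre``;
    the stretch of ROI i is xi[bin(d_i)] + psi[b_i] with psi drawn zero-mean.
    """
    cfg = config or PopulationConfig()
    if n_roi < 1 or n_batch < 1:
        raise ConfigError("need at least one ROI and one batch")
    if n_batch > n_roi:
        raise ConfigError(f"more batches ({n_batch}) than ROIs ({n_roi})")
    rng = np.random.default_rng(seed)

    lo, hi = cfg.depth_range
    edges = np.linspace(lo, hi, cfg.n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    xi = default_speed_profile(mids)
    psi = rng.normal(0.0, cfg.psi_sd, size=n_batch) if cfg.psi_sd > 0 else np.zeros(n_batch)
    batch_ids = tuple(f"batch{b:02d}" for b in range(n_batch))

    depths = rng.uniform(lo, hi, size=n_roi)
    batch_idx = rng.integers(0, n_batch, size=n_roi)
    # guarantee every batch is populated
    batch_idx[:n_batch] = np.arange(n_batch)
    bin_idx = np.clip(np.digitize(depths, edges[1:-1]), 0, cfg.n_bins - 1)

    rois = []
    for i in range(n_roi):
        pol = "On" if depths[i] < cfg.centre else "Off"
        mag = float(np.exp(rng.normal(0.0, cfg.amplitude_sigma)))
        rois.append(
            GroundTruthROI(
                roi_id=i,
                batch_id=batch_ids[batch_idx[i]],
                depth=float(depths[i]),
                polarity=pol,
                amplitude=mag if pol == "On" else -mag,
                offset=float(rng.normal(0.0, cfg.offset_sd)),
                stretch=float(xi[bin_idx[i]] + psi[batch_idx[i]]),
                noise_sigma=cfg.noise_sigma,
            )
        )
    truth = SimTruth(
        kernel_coef=default_kernel_coef(),
        xi=xi,
        psi=psi,
        bin_edges=edges,
        centre=cfg.centre,
        seed=seed,
        batch_ids=batch_ids,
        config=cfg,
    )
    return rois, truth


def population_table(rois: list[GroundTruthROI]) -> pd.DataFrame:
    """Tabulate a population as a DataFrame (one row per ROI)."""
    return pd.DataFrame(
        {
            "roi_id": [r.roi_id for r in rois],
            "batch": [r.batch_id for r in rois],
            "depth": [r.depth for r in rois],
            "polarity": [r.polarity for r in rois],
            "amplitude": [r.amplitude for r in rois],
            "offset": [r.offset for r in rois],
            "stretch": [r.stretch for r in rois],
            "noise_sigma": [r.noise_sigma for r in rois],
        }
    )


@dataclass
class SimTraces:
    """Simulated responses: noiseless model predictions and noisy repeats."""

    clean: np.ndarray          # (N, T)
    repeats: np.ndarray        # (N, R, T)
    rate_hz: float
    stimulus: ChirpStimulus


def simulate_traces(
    rois: list[GroundTruthROI],
    truth: SimTruth,
    stimulus: ChirpStimulus | None = None,
    repeats: int | None = None,
    seed: int = 0,
) -> SimTraces:
    """Generate repeat-structured traces from the encoding model plus noise.

    Each repeat is the LN-model prediction for the ROI's (alpha, a, beta,
    polarity) plus independent Gaussian noise of the ROI's noise_sigma.  With
    noise_sigma = 0 every repeat equals the exact model prediction.  The
    stimulus is z-scored before convolution (intensity units are arbitrary).
    """
    stim = stimulus or generate_chirp()
    reps = repeats if repeats is not None else truth.config.repeats
    if reps < 1:
        raise ConfigError("need at least one repeat")
    rng = np.random.default_rng(seed)

    x = stim.samples
    sd = np.std(x)
    xz = (x - np.mean(x)) / (sd if sd > 0 else 1.0)
    T = xz.size
    n = len(rois)
    clean = np.empty((n, T))
    for i, r in enumerate(rois):
        kern = build_kernel(truth.kernel_coef, r.stretch)
        clean[i] = predict_response(kern, r.amplitude, r.offset, xz, rate_hz=stim.rate_hz)
    sigmas = np.array([r.noise_sigma for r in rois])[:, None, None]
    noise = rng.standard_normal((n, reps, T)) * sigmas
    return SimTraces(clean=clean, repeats=clean[:, None, :] + noise, rate_hz=stim.rate_hz, stimulus=stim)


# --------------------------------------------------------------------------
# Pixel-level movies
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MovieConfig:
    """Scan-field geometry and rendering noise for synthetic x-z movies.

    Besides the target ROIs, the renderer plants larger "neuropil" structures
    (out-of-range sizes, temporally coherent but stimulus-independent signal)
    so that, as in real IPL scans where terminals tile most of each line, the
    per-line correlation thresholds sit in the signal range rather than at a
    noise quantile.
    """

    nx: int = 64
    nz: int = 56
    pixel_size_um: float = 1.0
    line_period_ms: float = 1.6
    artefact_lines: int = 6           # ~10 ms of ETL settling at 1.6 ms/line
    pixel_noise_sigma: float = 0.1
    background_level: float = 0.2
    roi_baseline: float = 1.0
    area_range_px: tuple[int, int] = (3, 7)
    gradient_range: tuple[float, float] = (0.8, 1.2)   # labelling gain from top to bottom z
    artefact_noise_sigma: float = 2.0
    margin_px: int = 1
    max_retries: int = 400
    z_band: tuple[int, int] | None = (8, 44)           # z-lines available for planting
    neuropil_coverage: float = 0.5                     # structure fraction per band line
    neuropil_area_range: tuple[int, int] = (12, 24)
    neuropil_amplitude: float = 0.18
    neuropil_smooth_frames: float = 5.0

    @property
    def frame_rate_hz(self) -> float:
        return 1000.0 / (self.line_period_ms * self.nz)


@dataclass
class Movie:
    """An x-z pixel movie (X x Z x frames) with its scan geometry."""

    pixels: np.ndarray
    pixel_size_um: float
    line_period_ms: float
    artefact_lines: int
    frame_rate_hz: float
    trigger_times: tuple[float, ...] = ()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class MovieTruth:
    """Planted footprints for end-to-end recovery tests.

    ``neuropil_mask`` marks the signal-carrying filler structures; pixels in
    neither ``masks`` nor ``neuropil_mask`` are pure background (noise only).
    """

    masks: np.ndarray            # (n_roi, X, Z) boolean
    centroids: np.ndarray        # (n_roi, 2) (x, z)
    roi_ids: np.ndarray          # ids into the population
    neuropil_mask: np.ndarray | None = None


def _grow_blob(rng, occupancy, nx, nz, z_lo, z_hi, area, margin):
    """Grow a 4-connected blob of ``area`` pixels at a random free location."""
    free = np.flatnonzero(~occupancy[:, z_lo:z_hi].ravel())
    if free.size == 0:
        return None
    pick = rng.choice(free)
    x0, z0 = pick // (z_hi - z_lo), z_lo + pick % (z_hi - z_lo)
    blob = {(x0, z0)}
    frontier = [(x0, z0)]
    while len(blob) < area and frontier:
        fx, fz = frontier[rng.integers(len(frontier))]
        nbrs = [(fx + dx, fz + dz) for dx, dz in ((1, 0), (-1, 0), (0, 1), (0, -1))]
        added = False
        for j in rng.permutation(4):
            cx, cz = nbrs[j]
            if 0 <= cx < nx and z_lo <= cz < z_hi and (cx, cz) not in blob and not occupancy[cx, cz]:
                blob.add((cx, cz))
                frontier.append((cx, cz))
                added = True
                break
        if not added:
            frontier.remove((fx, fz))
    if len(blob) < area:
        return None
    # reject if any blob pixel touches occupied space within the margin
    for cx, cz in blob:
        xs = slice(max(cx - margin, 0), min(cx + margin + 1, nx))
        zs = slice(max(cz - margin, 0), min(cz + margin + 1, nz))
        if occupancy[xs, zs].any():
            return None
    return blob


def render_movie(
    traces: SimTraces,
    rois: list[GroundTruthROI],
    config: MovieConfig | None = None,
    seed: int = 0,
) -> tuple[Movie, MovieTruth]:
    """Plant ROI blobs into a pixel field and render their traces as a movie.

    Each planted ROI is a connected blob whose pixels carry the ROI's noisy
    repeat trace (resampled to frame times) scaled by a depth-dependent
    labelling gradient, plus per-pixel Gaussian noise; background pixels carry
    baseline plus noise only.  The first ``artefact_lines`` z-lines of every
    frame are overwritten with high-variance values (ETL settling).
    """
    cfg = config or MovieConfig()
    if cfg.artefact_lines >= cfg.nz:
        raise ConfigError("artefact_lines must be smaller than the number of z lines")
    rng = np.random.default_rng(seed)
    n_roi = len(rois)

    if cfg.z_band is not None:
        z_lo, z_hi = cfg.z_band
        z_lo = max(z_lo, cfg.artefact_lines + 1)
        z_hi = min(z_hi, cfg.nz - 1)
    else:
        z_lo, z_hi = cfg.artefact_lines + 1, cfg.nz - 1
    occupancy = np.zeros((cfg.nx, cfg.nz), dtype=bool)
    masks = np.zeros((n_roi, cfg.nx, cfg.nz), dtype=bool)
    centroids = np.empty((n_roi, 2))
    for i in range(n_roi):
        area = int(rng.integers(cfg.area_range_px[0], cfg.area_range_px[1] + 1))
        blob = None
        for _ in range(cfg.max_retries):
            blob = _grow_blob(rng, occupancy, cfg.nx, cfg.nz, z_lo, z_hi, area, cfg.margin_px)
            if blob is not None:
                break
        if blob is None:
            raise PlacementError(
                f"could not place ROI {i} ({area} px) without overlap after "
                f"{cfg.max_retries} retries"
            )
        for cx, cz in blob:
            occupancy[cx, cz] = True
            masks[i, cx, cz] = True
        pts = np.array(sorted(blob))
        centroids[i] = pts.mean(axis=0)

    # neuropil fill: weakly coherent, stimulus-independent structures tile the
    # band (as terminals tile real IPL lines) until each line reaches the target
    # coverage; they may touch each other but keep a 1-px margin to the targets
    protected = np.zeros((cfg.nx, cfg.nz), dtype=bool)
    for cx, cz in np.argwhere(occupancy):
        xs = slice(max(cx - cfg.margin_px, 0), min(cx + cfg.margin_px + 1, cfg.nx))
        zs = slice(max(cz - cfg.margin_px, 0), min(cz + cfg.margin_px + 1, cfg.nz))
        protected[xs, zs] = True
    structure = occupancy.copy()
    distractor_masks: list[set] = []
    attempts = 0
    while attempts < 40 * cfg.max_retries:
        attempts += 1
        line_cov = structure[:, z_lo:z_hi].mean(axis=0)
        if line_cov.min() >= cfg.neuropil_coverage:
            break
        z_target = z_lo + int(np.argmin(line_cov))
        free_x = np.flatnonzero(~(structure[:, z_target] | protected[:, z_target]))
        if free_x.size == 0:
            # nothing placeable in the sparsest line; give up on it
            protected[:, z_target] = True
            continue
        x0 = int(rng.choice(free_x))
        area = int(rng.integers(cfg.neuropil_area_range[0], cfg.neuropil_area_range[1] + 1))
        blob = {(x0, z_target)}
        frontier = [(x0, z_target)]
        while len(blob) < area and frontier:
            fx, fz = frontier[rng.integers(len(frontier))]
            nbrs = [(fx + dx, fz + dz) for dx, dz in ((1, 0), (-1, 0), (0, 1), (0, -1))]
            added = False
            for j in rng.permutation(4):
                cx, cz = nbrs[j]
                if (
                    0 <= cx < cfg.nx and z_lo <= cz < z_hi
                    and (cx, cz) not in blob
                    and not structure[cx, cz] and not protected[cx, cz]
                ):
                    blob.add((cx, cz))
                    frontier.append((cx, cz))
                    added = True
                    break
            if not added:
                frontier.remove((fx, fz))
        for cx, cz in blob:
            structure[cx, cz] = True
        distractor_masks.append(blob)

    # continuous per-ROI signal: repeats laid out back to back, then resampled
    # to frame times (one extra second of tail so the last frame is covered)
    reps = traces.repeats.shape[1]
    dur = traces.stimulus.duration_s
    rate = traces.rate_hz
    total_s = reps * dur + 1.0
    n_frames = int(np.ceil(total_s * cfg.frame_rate_hz))
    t_frames = np.arange(n_frames) / cfg.frame_rate_hz
    t_sig = np.arange(int(round(reps * dur * rate))) / rate
    trigger_times = tuple(r * dur for r in range(reps))

    grad = np.linspace(cfg.gradient_range[0], cfg.gradient_range[1], cfg.nz)
    pixels = cfg.background_level + rng.standard_normal(
        (cfg.nx, cfg.nz, n_frames)
    ) * cfg.pixel_noise_sigma

    for i in range(n_roi):
        sig = traces.repeats[i].reshape(-1)
        sig_f = np.interp(t_frames, t_sig, sig, left=sig[0], right=sig[-1])
        for cx, cz in np.argwhere(masks[i]):
            pixels[cx, cz] += cfg.roi_baseline - cfg.background_level + grad[cz] * sig_f

    if distractor_masks:
        from scipy.ndimage import gaussian_filter1d

        for blob in distractor_masks:
            sig_f = cfg.neuropil_amplitude * gaussian_filter1d(
                rng.standard_normal(n_frames), cfg.neuropil_smooth_frames
            )
            for cx, cz in blob:
                pixels[cx, cz] += cfg.roi_baseline - cfg.background_level + grad[cz] * sig_f

    if cfg.artefact_lines > 0:
        pixels[:, : cfg.artefact_lines, :] = cfg.background_level + rng.standard_normal(
            (cfg.nx, cfg.artefact_lines, n_frames)
        ) * cfg.artefact_noise_sigma

    movie = Movie(
        pixels=pixels.astype(np.float32),
        pixel_size_um=cfg.pixel_size_um,
        line_period_ms=cfg.line_period_ms,
        artefact_lines=cfg.artefact_lines,
        frame_rate_hz=cfg.frame_rate_hz,
        trigger_times=trigger_times,
    )
    neuropil = np.zeros((cfg.nx, cfg.nz), dtype=bool)
    for blob in distractor_masks:
        for cx, cz in blob:
            neuropil[cx, cz] = True
    truth = MovieTruth(
        masks=masks,
        centroids=centroids,
        roi_ids=np.array([r.roi_id for r in rois]),
        neuropil_mask=neuropil,
    )
    return movie, truth


def write_movie_tiff(movie: Movie, path) -> None:
    """Export a movie as a multi-page TIFF (one page per frame, Z x X)."""
    import tifffile

    # (frames, Z, X) page layout; scan metadata in the image description
    stack = np.transpose(movie.pixels, (2, 1, 0)).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        metadata={
            "pixel_size_um": movie.pixel_size_um,
            "line_period_ms": movie.line_period_ms,
            "artefact_lines": movie.artefact_lines,
            "frame_rate_hz": movie.frame_rate_hz,
        },
    )
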