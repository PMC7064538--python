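"""Render a synthetic x-z glutamate movie and recover the planted ROIs.

Plants 30 bipolar-cell-terminal-sized blobs (plus neuropil filler) into a
64 x 56 pixel field, renders their chirp responses at 4 repeats, then runs the
full segmentation chain: local-correlation image, per-line 70th-percentile
thresholds, 4-connected region growing, 1-4 um diameter filter and the
repeat-reliability quality filter.
"""

import numpy as np

from iplscan import preprocess, rois, synth
from iplscan.stimulus import generate_chirp

stim = generate_chirp()
cfg = synth.PopulationConfig(noise_sigma=0.1)
population, truth = synth.sample_population(n_roi=30, n_batch=1, config=cfg, seed=1)
traces = synth.simulate_traces(population, truth, stim, repeats=4, seed=2)
movie, movie_truth = synth.render_movie(traces, population, seed=3)
print(f"movie: {movie.pixels.shape[0]}x{movie.pixels.shape[1]} px, "
      f"{movie.pixels.shape[2]} frames at {movie.frame_rate_hz:.1f} Hz "
      f"({movie.line_period_ms} ms/line, {movie.artefact_lines} artefact lines)")

ci = rois.correlation_image(movie)
thresholds = rois.line_thresholds(ci)
records = rois.filter_diameter(rois.grow_rois(ci, thresholds, movie), movie.pixel_size_um)
rois.extract_traces(movie, records)

good = []
for rec in records:
    _, _, repeat_raw = preprocess.preprocess_roi(
        rec.trace, movie.frame_rate_hz, movie.trigger_times, stim.duration_s
    )
    rec.quality_index = rois.quality_index(repeat_raw)
    if rec.quality_index >= 0.3:
        good.append(rec)

centroids = np.array([r.centroid for r in good])
errors = []
for c in movie_truth.centroids:
    d = np.sqrt(((centroids - c) ** 2).sum(axis=1)).min()
    if d <= 2.0:
        errors.append(d)

print(f"segmented {len(records)} in-range candidates, {len(good)} pass the "
      f"quality index (>= 0.3)")
print(f"recovered {len(errors)}/{len(movie_truth.centroids)} planted terminals, "
      f"mean centroid error {np.mean(errors):.2f} px")
print("every reported ROI lies within the 1-4 um effective-diameter bounds of "
      "bipolar-cell axon terminals; the quality filter rejects neuropil and noise.")
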