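"""Generate a synthetic two-photon movie with exact ground truth.

Builds a 256x256 px, 300-frame scene of 20 GCaMP-like somata, renders it,
and writes the movie (TIFF), ground-truth boxes (VOC XML), and noiseless
traces (CSV) to ./out_simulate/.
"""

from pathlib import Path

import numpy as np

from somatrace import image_io
from somatrace import synthetic_data as sd

out = Path("out_simulate")
out.mkdir(exist_ok=True)

config = sd.default_scene_config(noise_sigma=4.0)
scene = sd.generate_scene(config, seed=1)
stack, gt_boxes, gt_traces = sd.render_movie(scene)

image_io.write_movie(stack, out / "movie.tif")
image_io.write_voc_boxes(gt_boxes, out / "gt_boxes.xml", stack.fov_shape)
image_io.write_traces(gt_traces, out / "gt_traces.csv")

total_spikes = sum(len(c.spike_times) for c in scene.cells)
print(f"movie: {stack.n_frames} frames of {stack.fov_shape} px "
      f"at {stack.frame_rate} Hz, {stack.pixel_size} um/px")
print(f"cells: {len(scene.cells)}, total transients: {total_spikes}")
print(f"frame intensity: mean {stack.frames.mean():.1f} a.u., "
      f"std {stack.frames.std():.1f} a.u.")
# mean/std is the movie signal-to-noise ratio used to pick the frame
# downsampling; ~2 here, i.e. a realistically noisy acquisition
print(f"movie SNR (mean/std): {stack.frames.mean() / stack.frames.std():.2f}")
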