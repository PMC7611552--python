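"""Simulate a miniscope recording of a mating session and save it to disk.

Builds the published second-recording behavioral timeline (two
intromission bouts of 41.6 and 31.5 s around three anterior-thrusting
bouts of 2.4/4.6/1.1 s, ending in ejaculation), renders a 16-bit movie of
spiking GCaMP6s-like cells with neuropil contamination, photobleaching and
sensor noise, and writes the movie, ROI label mask, LED trace, epoch
script and ground-truth rates as plain files.
"""

from pathlib import Path

import halotrace as ht

out = Path("example_output")
out.mkdir(exist_ok=True)

cfg = ht.SimConfig(n_cells=8, image_shape=(64, 64), seed=1,
                   modulation_map=ht.mating_modulation(8, seed=1))
script = ht.generate_epoch_script(cfg, preset="male_day10")
movie, truth = ht.simulate_movie(cfg, script)
led = ht.simulate_led_trace(cfg)

ht.write_movie(movie, out / "movie.tif")
ht.write_label_mask(ht.RoiSet(truth.footprints), out / "rois.tif")
ht.write_led_trace(led, out / "led.csv")
script.to_csv(out / "epochs.csv")
cfg.to_file(out / "config.txt")

print(f"movie: {movie.n_frames} frames of {movie.image_shape} at "
      f"{movie.frame_rate:g} frames/s ({movie.duration:.1f} s)")
print(f"cells: {cfg.n_cells}, spikes per cell: "
      f"{[len(s) for s in truth.spike_times]}")
print(f"epochs: {', '.join(script.labels)}")
print(f"LED blinks at {led.rate:g} frames/s: one per imaging frame")
print(f"files written to {out}/")
print("Each cell's firing rate is modulated per epoch (0-30 Hz clip); the"
      " spike counts above reflect that modulation on top of the 3 Hz"
      " baseline.")
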