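"""Event-triggered averages of cell fluorescence around behavioral events.

Simulates a session, aligns the z-scored traces to the onsets of the AT
bouts, and prints the population-mean ETA around the event.
"""

import numpy as np

import halotrace as ht

session = ht.run_mating_session(seed=2, n_cells=8, image_shape=(48, 48))

onsets = ht.extract_event_onsets(session.script, "AT", edge="onset")
print(f"AT onsets (s): {onsets.tolist()}")

eta = ht.compute_eta(session.zscored, onsets, w_pre=10.0, w_post=10.0)
print(f"ETA over {eta.n_events} events, window "
      f"[{eta.lags_s[0]:g}, {eta.lags_s[-1]:g}] s, "
      f"{eta.cell_etas.shape[0]} cells")

pre = eta.population_mean[eta.lags_s < 0].mean()
post = eta.population_mean[(eta.lags_s >= 0) & (eta.lags_s < 5)].mean()
print(f"population mean z before onset: {pre:+.2f}, "
      f"0-5 s after onset: {post:+.2f}")
print("Cells carry the sign-flipped intromission pattern during AT, so the"
      " population-mean ETA shifts at the bout onset; per-cell rows in"
      " eta.cell_etas show which cells rise and which fall.")

peaks = eta.cell_etas[:, eta.lags_s >= 0].mean(axis=1)
print("per-cell mean z after onset:", np.round(peaks, 2).tolist())
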