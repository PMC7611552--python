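"""Behavior-epoch population statistics on a simulated mating session.

Reproduces the analysis structure of the epoch figures: per-cell epoch
means of z-scored ΔF/F0, the cross-behavior population-vector correlation
matrix, mean coefficients of determination, the cell sort key, and the
printed bout statistics with their t-test.
"""

import halotrace as ht

session = ht.run_mating_session(seed=1, n_cells=8, image_shape=(48, 48))

stats = session.epoch_statistics()
print("per-cell epoch means (z):")
print(stats.means.round(2).to_string())

corr = ht.population_correlation(stats, list(ht.MATING_LABELS))
print("\npopulation-vector correlations:")
print(corr.round(3).to_string())
print("\nAT is anticorrelated with intromission (the inverted firing"
      " pattern) while ejaculation is positively correlated (the amplified"
      " pattern).")

for label in ht.MATING_LABELS:
    print(f"mean r2 of {label} with the other mating behaviors: "
          f"{ht.mean_r2(corr, label):.3f}")
print("cells sorted by intromission mean:",
      ht.sort_cells(stats, "intromission"))

summary = ht.bout_statistics(session.script)
at = summary.table.loc["AT"]
intro = summary.table.loc["intromission"]
print(f"\nAT bouts: {summary.durations['AT'].round(1).tolist()} s -> "
      f"{at['mean_s']:.1f} +/- {at['std_s']:.1f} s")
print(f"intromission cumulative: {intro['cumulative_s']:.1f} s "
      f"across {int(intro['count'])} bouts")
t, df, p = ht.two_sample_ttest(summary.durations["AT"],
                               summary.durations["intromission"])
print(f"AT vs intromission durations: t = {t:.2f}, df = {df}, p = {p:.3f}")
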