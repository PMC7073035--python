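"""Score DSB repair pathway activity per cell on a small synthetic scene.

Builds a seeded droplet-style count matrix along a progenitor-to-photoreceptor
trajectory, computes the NHEJ/MMEJ/HDR scores (mean raw UMI count over each
curated gene set) and contrasts cycling vs postmitotic cells.
"""

from dsbscore import SimConfig, score_dsb, simulate_sc_trajectory

adata, truth = simulate_sc_trajectory(SimConfig(
    seed=0, n_cells={"progenitor": 300, "neuroblast": 200, "cone": 150, "rod": 150}))
scores = score_dsb(adata, species="human")

cycling = truth.obs["cycling"].to_numpy()
print(f"{adata.n_obs} cells, {adata.n_vars} genes")
print(f"{'pathway':8} {'cycling':>8} {'postmitotic':>12} {'excluded %':>11}")
for name, ps in scores.items():
    kept = ~ps.excluded.to_numpy()
    pre = ps.scores[cycling & kept].mean()
    post = ps.scores[~cycling & kept].mean()
    print(f"{name:8} {pre:8.2f} {post:12.2f} {100 * ps.excluded.mean():10.1f}%")

# The score is a mean raw count, so its units are UMIs per set gene. HDR
# collapses once cells exit the cell cycle, MMEJ settles at an intermediate
# level, NHEJ stays flat; cells with a zero score (all set genes dropped out)
# are flagged excluded and ignored in comparisons.
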