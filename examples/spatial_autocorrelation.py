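"""Is degradation clustered or diffuse? Moran's I of mid-lysis snapshots.

Computes the median Moran's I of degraded-doublet counts at 54% total
degradation over 300 qualifying runs, for baseline rates and for a faster
exposure/degradation variant. Higher I means degradation is more spatially
clustered around where plasmin is working.
"""

from fiberlysis import FiberSpec, RateSet, ensemble_moran

fiber = FiberSpec(72.7)
for label, rates in [
    ("baseline (k_deg = k_exp = 5/s)", RateSet()),
    ("fast exposure/degradation (45/s)", RateSet(0.05, 57.6, 45, 45)),
]:
    res = ensemble_moran(fiber, rates, snapshot_fraction=0.54,
                         n_maps=300, master_seed=4)
    print(f"{label}: median Moran's I = {res.median_i:.3f} "
          f"({len(res.i_values)} maps from {res.n_attempts} runs)")

print()
print("Expected I under spatial randomness is -1/(n-1) = -0.021 for the")
print("49-protofibril grid; both scenarios are strongly clustered, and")
print("faster local degradation clusters more: plasmin chews through its")
print("surroundings before crawling away.")
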