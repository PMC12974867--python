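"""Generate a synthetic four-tree isotope study with known ground truth.

The generator emulates a semi-arid dendro-isotope campaign: ~700 years of
rainfall with a drying trend and centennial wet/dry cycles, four slow-
growing cores sampled from bark to pith (one with a 1500–1700 CE growth
hiatus), 12–15 radiocarbon dates per core, and the post-1850 atmospheric
δ13C decline and CO2 rise embedded in the measurements.
"""

from dendroiso import generate_world

world = generate_world(seed=1)

print(f"rainfall: {world.rainfall.span[0]}–{world.rainfall.span[1]} CE, "
      f"mean {world.rainfall.values.mean():.0f} mm/yr")
for tid, series in world.trees.items():
    ages = world.true_ages[tid]
    cfg = world.tree_configs[tid]
    hiatus = f", hiatus {cfg.hiatus[0]:.0f}–{cfg.hiatus[1]:.0f} CE" \
        if cfg.hiatus else ""
    print(f"{tid}: {len(series)} samples, true ages "
          f"{ages.min():.0f}–{ages.max():.0f} CE, "
          f"{len(world.dates[tid])} AMS dates{hiatus}")

# Every observable regenerates bit-identically from the seed; the truth
# (rainfall, per-sample ages, tie points) rides along for recovery tests.
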