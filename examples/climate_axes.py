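"""Reduce monthly climate to six statistics and the TH/AI axes.

Each land cell contributes mean, variability, and Colwell predictability
of temperature and precipitation; a correlation PCA over cells yields
temperature harshness (PC1) and aridity index (PC2), sign-anchored so
harsh/arid regimes score high.
"""

from ecobarriers.climate_components import env_pca, summarize_series
from ecobarriers.synthetic_world import WorldConfig, generate_climate

config = WorldConfig(grid_n_lat=15, grid_n_lon=20, years=30, seed=2)
temperature, precipitation = generate_climate(config)
summary = summarize_series(temperature, precipitation)
axes = env_pca(summary)

print("per-cell climate summary (first rows):")
print(summary.table.head(3).round(2).to_string(index=False))
print("\ncomponent loadings:")
print(axes.loadings.round(2))
print(f"\nexplained variance: TH {axes.explained_variance[0]:.0%}, "
      f"AI {axes.explained_variance[1]:.0%}")
# temp_mean loads negatively on TH (cold = harsh) and precip_mean
# negatively on AI (dry = arid); variability loads positively on both.
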