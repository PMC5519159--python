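"""Classify wasted seed dispersal from plots and dung piles.

Vegetation plots give the species' survival limit (the minimum modelled
suitability where living plants occur); dung piles whose seeds land
strictly below that limit are wasted dispersal events.
"""


from seedwaste import (
    SeedCountModel,
    ThresholdLogisticOccupancy,
    TrueSuitabilityParams,
    classify_wasted,
    estimate_survival_limit,
    generate_island,
    sample_dung_piles,
    sample_plots,
    seed_stats,
    summarize_distribution,
    true_suitability,
    wasted_report,
)

island = generate_island(seed=2, n_rows=100, n_cols=100)
truth = true_suitability(island, TrueSuitabilityParams(
    intercept=-1.0, coefficients={"precip_dry": 2.2, "precip_wet": 1.2}))
responses = {"guava": (truth, ThresholdLogisticOccupancy(threshold=0.35, a=-1.0, b=4.0))}
count_models = {"guava": SeedCountModel(presence_prob=0.44, mean_seeds=1443.0, dispersion=0.5)}

plots = sample_plots(island, responses, "LR", (10, 400), seed=6)
plots += sample_plots(island, responses, "CF", (100, 400), seed=7)
piles = sample_dung_piles(island, "LR", 159, count_models, seed=8)
piles += sample_dung_piles(island, "CF", 63, count_models, seed=9)

stats = seed_stats(piles, "guava")
print(f"{stats.total_seeds} guava seeds in {stats.n_positive_piles} of "
      f"{stats.n_piles} piles (positive-pile mean {stats.mean_per_positive_pile:.0f}, "
      f"SD {stats.sd_per_positive_pile:.0f}, max {stats.max_count})")

# here the true surface stands in for a fitted one (see example 02)
limit = estimate_survival_limit(plots, truth, "guava")
print(f"survival limit (minimum suitability over occupied plots): {limit.limit:.3f}")

plot_sum = summarize_distribution([p for p in plots if p.site == "LR"], truth, "guava", "plot")
pile_sum = summarize_distribution([p for p in piles if p.site == "LR"], truth, "guava", "pile")
print(f"LR plots:  suitability range {plot_sum.suitability_min:.3f}-{plot_sum.suitability_max:.3f}")
print(f"LR piles:  suitability range {pile_sum.suitability_min:.3f}-{pile_sum.suitability_max:.3f}")

flags = classify_wasted(piles, truth, limit, "guava")
report = wasted_report(piles, flags, "guava")
print(f"wasted: {report.n_piles_below} piles "
      f"({report.pct_of_species_piles:.1f}% of seed-bearing piles, "
      f"{report.pct_of_all_piles:.1f}% of all piles), "
      f"{report.pct_seeds_wasted:.1f}% of all seeds")
# Piles reach well below the lowest suitability at which plants grow:
# the tortoises carry seeds into habitat where they cannot establish.
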