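# Default synthetic-landscape specification: an 8-class vegetation mosaic with the
# class shares and per-class NDVI band targets of the packaged study configuration.
# Shares are the published percentages; they sum to 100.01% and are renormalized on load.
n_rows: 500
n_cols: 500
pixel_size_m: 10.0
classes:
  - {code: 1, name: remnant_forest, proportion: 0.3098, ndvi_mean: 0.79, ndvi_sd: 0.05}
  - {code: 2, name: disturbed_forest, proportion: 0.0653, ndvi_mean: 0.75, ndvi_sd: 0.05}
  - {code: 3, name: savanna_grassland, proportion: 0.2447, ndvi_mean: 0.53, ndvi_sd: 0.05}
  - {code: 4, name: grassland, proportion: 0.0608, ndvi_mean: 0.71, ndvi_sd: 0.05}
  - {code: 5, name: wetland, proportion: 0.0435, ndvi_mean: 0.74, ndvi_sd: 0.05}
  - {code: 6, name: coffee_plantation, proportion: 0.08, ndvi_mean: 0.83, ndvi_sd: 0.05}
  - {code: 7, name: farmland, proportion: 0.1923, ndvi_mean: 0.584, ndvi_sd: 0.05}
  - {code: 8, name: built_up, proportion: 0.0037, ndvi_mean: 0.20, ndvi_sd: 0.05}
# Row-normalized label-confusion probabilities for reference-point simulation.
# Diagonal entries are the published per-class producer accuracies; the remaining
# probability mass is spread uniformly over the other classes.
confusion:
  points_per_class: 100
  producer_accuracy:
    1: 0.844
    2: 0.429
    3: 0.825
    4: 0.943
    5: 0.767
    6: 0.412
    7: 0.870
    8: 0.929
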