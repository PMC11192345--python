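# esval

Benefit-transfer **e**cosystem-**s**ervice **val**uation of categorical
vegetation-cover maps, built for landscape ecologists and environmental
economists who need a transparent, reproducible route from a classified
land-cover map (or a per-class area table) to annual monetary values,
elasticity diagnostics and thematic-map accuracy metrics.

The packaged study configuration is an Afromontane landscape in
southwestern Ethiopia with seven valued vegetation classes (remnant
forest, disturbed forest, savanna grassland, grassland, wetland, coffee
plantation, farmland) over a 472,118-ha mapped region.

## The model

Each land-cover class *k* with area *A_k* (ha) carries a per-hectare annual
value coefficient *VC_kf* (USD ha⁻¹ yr⁻¹) for each service function *f*
(grouped into the four Millennium-Ecosystem-Assessment categories:
supporting, regulating, provisioning, cultural):

```
ESV_k = Σ_f A_k · VC_kf      ESV_f = Σ_k A_k · VC_kf      ESV = Σ_k Σ_f A_k · VC_kf
```

Coefficients are assembled from three routes:

* **benefit transfer** — unit values from comparable study sites, each with
  an explicit adjustment factor (inflation / site correction);
* **social cost of carbon** — per-class carbon stock (t C ha⁻¹) × 44/12
  (the CO₂/C molar-mass ratio) × SCC (USD per t CO₂; packaged value 1.47),
  entering as the climate-regulation function;
* **direct market value** — e.g. coffee: production rate × price × (1 −
  cost fraction).

The **coefficient of sensitivity** is the elasticity of ESV to a ±50%
perturbation of one class's coefficients,
`CS = |ΔESV/ESV| / |ΔVC/VC|`. Because ESV_k is linear in its coefficients,
per-class CS is identically 1; in "total" mode CS equals the class's share
of total value. Map quality is assessed with a confusion matrix, overall
accuracy, Cohen's kappa and per-class producer/user accuracies, and a
seeded synthetic-landscape generator stands in for the satellite stage so
the whole chain is testable offline.

## Worked example

```bash
esval --quiet value
```

prints the per-class valuation of the packaged configuration (areas ×
coefficient table), ending with:

```
 class_code        class_name   area_ha  ...  cultural_million_usd  total_million_usd
          1    remnant_forest 146929.50  ...                35.469            882.738
          5           wetland  18396.11  ...                52.387            170.979
          6 coffee_plantation  41893.27  ...                 0.176            269.784
          7          farmland  94844.59  ...                 0.000            225.152
total ESV: 2089.061 million USD/yr (2.089 billion)
```

Remnant forest dominates the total (883 M USD yr⁻¹, driven by its
146,930 ha and high supporting/regulating coefficients); wetlands, only
18,396 ha, still contribute 171 M USD yr⁻¹ because their regulating
(5063.9 USD ha⁻¹ yr⁻¹) and cultural (2847.7) coefficients are the highest
of any class. The grand total is 2.089 billion USD per year.

```bash
esval --quiet sensitivity          # per-class CS = 1.0 for every class (exact)
esval --quiet run --out results/   # full pipeline: CSV tables + summary.json
esval simulate --seed 7 --out sim/ # synthetic landscape, bands, reference points
esval areas sim/landcover.asc      # per-class hectares and shares
esval accuracy sim/reference_points.csv
```

From Python:

```python
from esval import datasets, esv_total
report = esv_total(datasets.load_area_table("valuation"),
                   datasets.load_service_coefficients())
print(report.total_billion_usd)    # 2.089
```

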