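"""Simulate batch and fed-batch yeast fermentations and render Raman spectra.

Builds the full synthetic study layout — three calibration batches, one unseen
validation batch, a three-bolus fed-batch, and single-compound titrations —
and prints the sample counts, concentration ranges and the analyte
cross-correlation structure of the calibration set.
"""

import ramanferm as rf

scenario = rf.generate_transfer_scenario(seed=1)

print("Datasets")
for name, ds in (("calibration (3 batches)", scenario.base_calibration),
                 ("validation batch", scenario.validation_batch),
                 ("fed-batch", scenario.fed_batch)):
    g, e, b = (ds.reference(a) for a in ("glucose", "ethanol", "biomass"))
    print(f"  {name:24s} {ds.n_samples:3d} spectra | glucose {g.min():6.1f}-{g.max():6.1f} mM"
          f" | ethanol {e.min():6.1f}-{e.max():6.1f} mM | biomass {b.min():5.2f}-{b.max():5.2f} g/L")

for analyte, series in scenario.titrations.items():
    print(f"  titration {analyte:9s} {series.levels.size:3d} levels x "
          f"{series.replicate_count} replicates, up to {series.concentrations.max():.2f}")

corr = rf.pearson_matrix(scenario.base_calibration.reference_table())
print("\nPearson correlations of the calibration references (the cross-correlation")
print("problem: substrate, product and biomass co-vary almost perfectly):")
print(corr.values.round(4).to_string())
print(f"min |r| off-diagonal: {corr.min_abs_offdiagonal():.4f}")
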