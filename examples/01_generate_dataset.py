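"""Regenerate the full-scale flow-curve dataset and inspect it.

The eight canonical alginate/gelatin/TO-NFC compositions are swept over
21 log-spaced shear rates (0.1-100 1/s); viscosities and shear stresses
come from the characterized Cross and Herschel-Bulkley parameter sets,
with 5% multiplicative log-normal noise emulating instrument scatter.
"""

from bioinkflow import datasets

dataset = datasets.generate_dataset(noise_sigma=0.05, seed=42)
print(f"{len(dataset)} rows, {len(dataset.compositions)} compositions")
print(dataset.frame.head(8).to_string(index=False))

datasets.write_dataset(dataset, "flow_curves.csv")
print("\nwrote flow_curves.csv (+ flow_curves.csv.meta.json)")

# round trip through the CSV contract
clone = datasets.read_dataset("flow_curves.csv")
assert len(clone) == len(dataset)
print("round trip OK")
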