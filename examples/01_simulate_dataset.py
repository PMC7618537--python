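"""Generate a synthetic vial study and write it to CSV.

Each vial is measured six times; every measurement is a pair of spectra
(zero-offset: wall-dominated, offset: content-enriched) built from the
two-layer glass/content mixing model with shot-like noise.
"""

import sorscreen as sc
from sorscreen import io

pairs = sc.generate_dataset(
    classes=["genuine", "saline", "sucrose"],
    n_vials=5, replicates=6, seed=0,
)
io.write_pairs_csv(pairs, "scratch_pairs.csv")

classes = sorted({p.class_label for p in pairs})
vials = len({p.vial_id for p in pairs})
print(f"{len(pairs)} SORS pairs written ({vials} vials, classes: {classes})")
print("one pair:", pairs[0].measurement_id, "batch", pairs[0].batch)
# 90 pairs = 3 classes × 5 vials × 6 replicate measurements; the CSV holds
# 180 spectra (two acquisition roles per measurement) plus a metadata sidecar.
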