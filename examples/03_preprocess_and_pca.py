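"""Condition separated spectra and inspect class structure with PCA.

The chain truncates to 760–1720 cm⁻¹, removes a 5th-order polynomial
background per spectrum, applies SNV, and mean-centres.  PCA scores of
genuine vs saline separate along the first components; each class gets a
95% confidence ellipse in the score plane.
"""

import numpy as np
import sorscreen as sc
from sorscreen import chemometrics, preprocessing, separation

pairs = sc.generate_dataset(["genuine", "saline"], n_vials=6, replicates=6, seed=2)
sset, _ = separation.separate_dataset(pairs)
pre = preprocessing.preprocess_set(sset)

pca = chemometrics.pca_fit(pre, 2)
print("explained variance ratio:",
      ", ".join(f"{v:.3f}" for v in pca.explained_variance_ratio))

for cls in ("genuine", "saline"):
    rows = pre.class_rows(cls)
    ell = chemometrics.confidence_ellipse(pca.scores[rows, :2])
    inside = np.mean(ell.contains(pca.scores[rows, :2]))
    print(f"{cls}: score centre {ell.center.round(2)}, "
          f"{100 * inside:.0f}% of its points inside the 95% ellipse")
# Most of the variance lies on PC1 because the saline content lacks the
# sucrose/ethanol bands entirely; the ellipses summarise per-class scatter.
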