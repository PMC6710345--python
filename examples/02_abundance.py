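"""From qPCR triplicates to 16S-normalized relative abundances.

Builds a tiny triplicate Ct dataset for two genes plus the 16S rRNA gene,
collapses replicates (mean of detected; <2 detected = non-detect), and
normalizes per 16S copies.
"""

import pandas as pd

from soilrisknet import abundance as ab

slope, intercept = -3.32, 37.0
rows = []
for sample, (ct_ars, ct_sul, ct_16s) in {
    "s1": (24.0, 28.0, 12.0),
    "s2": (23.5, 31.0, 11.8),
}.items():
    for gene, ct in (("arsC", ct_ars), ("sulII", ct_sul), ("16S", ct_16s)):
        for rep in (1, 2, 3):
            detected = not (gene == "sulII" and sample == "s2" and rep > 1)
            copies = float(ab.standard_curve_quantify(ct + 0.1 * rep, slope, intercept))
            rows.append((sample, gene, rep, copies if detected else 0.0, detected))

long = pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "value", "detected"])
table = ab.collapse_replicates(long, min_detect=2)
print("Absolute copies (sulII in s2 amplified only once -> non-detect 0):")
print(table.data.round(1))

panel = ab.validate_panel(pd.DataFrame({
    "gene": ["arsC", "sulII", "16S"],
    "class": ["MRG", "ARG", "16S"],
    "subclass": ["arsenic", "sulfonamide", "ribosomal"],
}))
rel = ab.normalize_to_16s(table, panel)
print("\nRelative abundance (copies per 16S copy; ~fraction of bacteria carrying the gene):")
print(rel)
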