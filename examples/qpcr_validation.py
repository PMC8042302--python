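"""2^-ddCt relative quantification and sign agreement with sequencing.

Builds a small Ct table (target gene + Gapdh2 endogenous control, three
biological x two technical replicates) for a hybrid and one parent, then
checks that the qPCR log2 fold change agrees in sign with a sequencing
contrast's M value.
"""

import pandas as pd

from hybridtrio import compare_to_wts, delta_delta_ct

rows = []
cts = {
    # sample -> (target Ct around, control Ct around)
    "hybrid": (21.0, 18.0),   # target 3 cycles after control
    "parent1": (23.0, 18.0),  # target 5 cycles after control -> lower expression
}
for sample, (tgt, ctl) in cts.items():
    for bio in (1, 2, 3):
        for tech in (1, 2):
            jitter = 0.05 * ((bio + tech) % 3 - 1)
            rows.append(["vg", sample, "target", bio, tech, tgt + jitter])
            rows.append(["Gapdh2", sample, "endogenous_control", bio, tech, ctl + jitter])
ct = pd.DataFrame(rows, columns=["gene_id", "sample_id", "role", "bio_rep", "tech_rep", "Ct"])

folds = delta_delta_ct(ct, "vg", calibrator_sample="parent1")
print(folds.round(3).to_string())

wts = pd.DataFrame({"M": [1.8]}, index=["vg"])  # sequencing log2FC, hybrid over parent1
qpcr_log2fc = pd.Series({"vg": folds.loc["hybrid", "log2_fold"]})
table, agreement = compare_to_wts(qpcr_log2fc, wts)
print(f"\nsign agreement with sequencing: {agreement:.0%}")
# The hybrid reaches threshold two cycles before the parent relative to the
# control, i.e. ~4-fold higher expression (fold ~= 4, log2 fold ~= +2),
# matching the positive sequencing fold change.
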