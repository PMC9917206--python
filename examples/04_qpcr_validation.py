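"""qPCR validation of RNA-seq fold changes.

Generates a qPCR Ct table for six genes spanning the planted fold-change
range, quantifies each gene by 2^-dCt against a two-gene housekeeping panel,
and rank-correlates the qPCR Z+ vs A+ log2 fold changes with the truth.
"""

from genospec.qpcr import qpcr_fold_changes, relative_expression, validate_against_rnaseq
from genospec.simulate import GroundTruth, generate_qpcr

# one worked quantification: Ct 25 against housekeeping means 20 and 20
dct, rel = relative_expression([25.0], [[20.0], [20.0]])
print(f"dCt = {dct:.1f}  ->  relative expression = 2^-dCt x 10,000 = {rel:.1f}")

truth = GroundTruth(true_lfc={"mvk": -2.8, "fdps": -2.1, "lss": -1.4,
                              "atg101": 0.8, "map1lc3a": 1.3, "bnip4": 2.0})
table = generate_qpcr(truth, list(truth.true_lfc), noise_sd=0.2, seed=1)
qpcr_lfcs = qpcr_fold_changes(table, "Z+", "A+")
rho, p, paired = validate_against_rnaseq(qpcr_lfcs, truth.true_lfc)

print(paired.to_string(index=False))
print(f"Spearman rho = {rho:.4f}, exact permutation p = {p:.5f}")
# rho near 1 at 0.2-cycle noise: the qPCR assay reproduces the ranking of
# the RNA-seq fold changes, validating the differential calls.
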